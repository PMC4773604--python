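"""Construction of the Case A / Case B cerebellar network topologies.

The circuit is the IO-PC-DCN subcircuit with a simplified granular layer:
100 mossy fibres (MF), 2000 granule cells (GC), and per *microcomplex* one
climbing fibre (CF), a group of 10 Purkinje cells (PC) and one deep-nuclei
cell (DCN). Case A has one agonist/antagonist microcomplex pair (2 CF, 20
PC, 2 DCN); Case B has three pairs, one per controlled joint (6 CF, 60 PC,
6 DCN). Synapse counts follow the reference connectivity of the model:

==========  =========  =======  =======
projection  rule       Case A   Case B
==========  =========  =======  =======
MF->GC      4 random per GC  8000   8000
MF->DCN     all-to-all        200    600
CF->PC      1 per CF-PC pair   20     60
GC->PC      all-to-all      40000  120000
PC->DCN     own microcomplex   20     60
==========  =========  =======  =======

Weights are non-negative conductances; whether a projection inhibits is a
property of the projection, not of the weight's sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lif import LIFParameters

__all__ = [
    "CaseConfig",
    "Projection",
    "Microcomplex",
    "NetworkTopology",
    "build_network",
    "microcomplex_of",
    "snapshot_weights",
    "PC_PER_MICROCOMPLEX",
]

PC_PER_MICROCOMPLEX = 10

# Population-specific membrane parameter sets. PCs and DCNs are large cells
# integrating thousands of afferents; their capacitance/leak are sized so
# that the 5 nS initial PF weight (4 coincident PF spikes per 2 ms step)
# drives PCs at a graded ~100 Hz simple-spike rate, comparable to the deep
# nuclei operating range (a requirement for the inhibitory pair rule to
# balance potentiation against depression). DCN cells rest near threshold
# (-60 mV): a small mossy-fibre drive starts them, and Purkinje inhibition
# gates them effectively, keeping postsynaptic spikes available to the
# nuclear plasticity rules.
DEFAULT_LIF = {
    "MF": LIFParameters(),
    "GC": LIFParameters(),
    "PC": LIFParameters(membrane_capacitance=100.0, leak_conductance=12.0),
    "CF": LIFParameters(),
    "DCN": LIFParameters(
        membrane_capacitance=30.0, leak_conductance=3.0,
        resting_potential=-60.0, tau_inh=0.010
    ),
}


@dataclass(frozen=True)
class CaseConfig:
    """Structural configuration of one case study."""

    case: str = "A"
    n_mf: int = 100
    n_gc: int = 2000
    pfpc_init_weight: float = 5.0  # nS
    mfdcn_init_weight: float = 0.0  # nS
    pcdcn_init_mode: str = "fixed"  # zero | random | fixed | high
    pcdcn_fixed_weight: float = 1.2  # nS, calibration value for 'fixed'
    pcdcn_high_weight: float = 3.6  # nS for 'high' (and the cap for 'random')
    cfpc_weight: float = 2000.0  # nS, effectively forces the complex spike
    mf_gc_fan_in: int = 4

    def __post_init__(self):
        if self.case not in ("A", "B"):
            raise ValueError("case must be 'A' or 'B'")
        if self.pcdcn_init_mode not in ("zero", "random", "fixed", "high"):
            raise ValueError(f"unknown pcdcn_init_mode {self.pcdcn_init_mode!r}")

    @property
    def n_joints(self) -> int:
        return 1 if self.case == "A" else 3

    @property
    def n_microcomplexes(self) -> int:
        return 2 * self.n_joints

    @property
    def n_pc(self) -> int:
        return PC_PER_MICROCOMPLEX * self.n_microcomplexes

    @property
    def n_cf(self) -> int:
        return self.n_microcomplexes

    @property
    def n_dcn(self) -> int:
        return self.n_microcomplexes


@dataclass
class Projection:
    """Explicit synapse table of one projection."""

    pre: str
    post: str
    pre_ids: np.ndarray
    post_ids: np.ndarray
    weights: np.ndarray  # nS, >= 0
    kind: str  # 'exc' | 'inh'
    plasticity: str | None = None  # tag of the rule acting here

    def __len__(self) -> int:
        return len(self.weights)

    def as_matrix(self, n_pre: int, n_post: int) -> np.ndarray:
        m = np.zeros((n_pre, n_post))
        m[self.pre_ids, self.post_ids] = self.weights
        return m

    def set_from_matrix(self, m: np.ndarray) -> None:
        self.weights = np.ascontiguousarray(m[self.pre_ids, self.post_ids])


@dataclass(frozen=True)
class Microcomplex:
    """One functional unit CF -> PC group -> DCN cell."""

    index: int
    cf: int
    pcs: tuple
    dcn: int
    sign: int  # +1 agonist (positive error), -1 antagonist
    joint: int


@dataclass
class NetworkTopology:
    """Populations, projections and microcomplex bookkeeping of one case."""

    config: CaseConfig
    populations: dict  # name -> (size, LIFParameters)
    projections: dict  # name -> Projection
    microcomplexes: list
    seed: int
    offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        off = 0
        for name, (size, _p) in self.populations.items():
            self.offsets[name] = off
            off += size
        self.n_neurons = off

    def population_of(self, neuron_id: int) -> tuple[str, int]:
        if not 0 <= neuron_id < self.n_neurons:
            raise ValueError(f"neuron id {neuron_id} outside network of {self.n_neurons}")
        for name, (size, _p) in self.populations.items():
            base = self.offsets[name]
            if base <= neuron_id < base + size:
                return name, neuron_id - base
        raise AssertionError("unreachable")

    def synapse_counts(self) -> dict:
        return {name: len(proj) for name, proj in self.projections.items()}


def build_network(
    config: CaseConfig,
    seed: int = 0,
    lif_params: dict | None = None,
) -> NetworkTopology:
    """Build the full topology of the requested case.

    The only randomised wiring is the MF->GC fan-in (4 distinct MFs per GC,
    drawn from a generator seeded with ``seed``) and, if
    ``pcdcn_init_mode='random'``, the initial PC->DCN weights.
    """
    rng = np.random.default_rng(seed)
    params = dict(DEFAULT_LIF)
    if lif_params:
        params.update(lif_params)

    populations = {
        "MF": (config.n_mf, params["MF"]),
        "GC": (config.n_gc, params["GC"]),
        "PC": (config.n_pc, params["PC"]),
        "CF": (config.n_cf, params["CF"]),
        "DCN": (config.n_dcn, params["DCN"]),
    }

    # MF -> GC: each GC receives fan_in distinct randomly chosen MFs
    fan = config.mf_gc_fan_in
    mf_of_gc = np.empty((config.n_gc, fan), dtype=np.int64)
    for g in range(config.n_gc):
        mf_of_gc[g] = rng.choice(config.n_mf, size=fan, replace=False)
    mfgc = Projection(
        pre="MF", post="GC",
        pre_ids=mf_of_gc.ravel(),
        post_ids=np.repeat(np.arange(config.n_gc), fan),
        weights=np.ones(config.n_gc * fan),
        kind="exc",
    )

    # MF -> DCN: complete bipartite, plastic
    mf_ids = np.repeat(np.arange(config.n_mf), config.n_dcn)
    dcn_ids = np.tile(np.arange(config.n_dcn), config.n_mf)
    mfdcn = Projection(
        pre="MF", post="DCN", pre_ids=mf_ids, post_ids=dcn_ids,
        weights=np.full(config.n_mf * config.n_dcn, float(config.mfdcn_init_weight)),
        kind="exc", plasticity="mfdcn",
    )

    # CF -> PC: each CF contacts its 10-PC group, one synapse per pair
    cf_ids = np.repeat(np.arange(config.n_cf), PC_PER_MICROCOMPLEX)
    pc_ids = np.arange(config.n_pc)
    cfpc = Projection(
        pre="CF", post="PC", pre_ids=cf_ids, post_ids=pc_ids,
        weights=np.full(config.n_pc, float(config.cfpc_weight)),
        kind="exc",
    )

    # GC -> PC: complete bipartite, plastic (the PF synapses)
    gc_ids = np.repeat(np.arange(config.n_gc), config.n_pc)
    pc_all = np.tile(np.arange(config.n_pc), config.n_gc)
    gcpc = Projection(
        pre="GC", post="PC", pre_ids=gc_ids, post_ids=pc_all,
        weights=np.full(config.n_gc * config.n_pc, float(config.pfpc_init_weight)),
        kind="exc", plasticity="pfpc",
    )

    # PC -> DCN: each PC inhibits only its microcomplex's DCN cell
    pcdcn_pre = np.arange(config.n_pc)
    pcdcn_post = pcdcn_pre // PC_PER_MICROCOMPLEX
    if config.pcdcn_init_mode == "zero":
        w0 = np.zeros(config.n_pc)
    elif config.pcdcn_init_mode == "fixed":
        w0 = np.full(config.n_pc, float(config.pcdcn_fixed_weight))
    elif config.pcdcn_init_mode == "high":
        w0 = np.full(config.n_pc, float(config.pcdcn_high_weight))
    else:  # random
        w0 = rng.uniform(0.0, config.pcdcn_high_weight, config.n_pc)
    pcdcn = Projection(
        pre="PC", post="DCN", pre_ids=pcdcn_pre, post_ids=pcdcn_post,
        weights=w0, kind="inh", plasticity="pcdcn",
    )

    microcomplexes = [
        Microcomplex(
            index=m,
            cf=m,
            pcs=tuple(range(m * PC_PER_MICROCOMPLEX, (m + 1) * PC_PER_MICROCOMPLEX)),
            dcn=m,
            sign=+1 if m % 2 == 0 else -1,
            joint=m // 2,
        )
        for m in range(config.n_microcomplexes)
    ]

    return NetworkTopology(
        config=config,
        populations=populations,
        projections={
            "MF->GC": mfgc,
            "MF->DCN": mfdcn,
            "CF->PC": cfpc,
            "GC->PC": gcpc,
            "PC->DCN": pcdcn,
        },
        microcomplexes=microcomplexes,
        seed=seed,
    )


def microcomplex_of(neuron_id: int, topology: NetworkTopology) -> tuple[int, int]:
    """Microcomplex index and sign (+1/-1) of a PC, CF or DCN neuron.

    ``neuron_id`` is the global index; MF/GC inputs are not microzone
    members and raise ``ValueError``.
    """
    pop, local = topology.population_of(neuron_id)
    if pop in ("MF", "GC"):
        raise ValueError(f"{pop} cells do not belong to a microcomplex")
    m = local // PC_PER_MICROCOMPLEX if pop == "PC" else local
    mc = topology.microcomplexes[m]
    return mc.index, mc.sign


def snapshot_weights(topology: NetworkTopology) -> dict:
    """Weight tables keyed by projection name.

    Each value is a structured copy (pre_id, post_id, weight_nS) suitable
    for lossless CSV round-tripping.
    """
    out = {}
    for name, proj in topology.projections.items():
        out[name] = {
            "pre_id": proj.pre_ids.copy(),
            "post_id": proj.post_ids.copy(),
            "weight_nS": proj.weights.copy(),
        }
    return out
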