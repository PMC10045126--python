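"""Backwards-in-time coalescent simulation over explicit demographic
scenarios, with microsatellite (SMM/GSM) and mtDNA sequence mutation
layers.

The demographic model is the one used for the chukar partridge ABC
analysis: four populations (Thrace, West, East, Central Anatolia)
related by split events and a single admixture event that creates the
Central Anatolian population from West and East donors with admixture
rate ``ra``.  Three built-in scenario topologies differ in the order
of the splits (see :func:`builtin_scenario`).

Simulation uses the continuous-time Kingman coalescent: within each
population k lineages coalesce at rate k(k-1)/2 / s per generation,
where s is the haploid number of gene copies (2N for diploid autosomal
loci, N_f for mtDNA).  There is no migration outside the admixture
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .io_formats import GenotypeMatrix, SequenceAlignment

__all__ = [
    "DemographicEvent",
    "ScenarioSpec",
    "MutationModel",
    "Genealogy",
    "builtin_scenario",
    "SCENARIO_POPS",
    "simulate_genealogy",
    "mutate_microsat",
    "simulate_msat_dataset",
    "simulate_mtdna",
]

SCENARIO_POPS = ["thrace", "west", "east", "central"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# transition partner and the two transversion partners per base
_TRANSITION = {b"A": b"G", b"G": b"A", b"C": b"T", b"T": b"C"}
_TRANSVERSIONS = {b"A": (b"C", b"T"), b"G": (b"C", b"T"),
                  b"C": (b"A", b"G"), b"T": (b"A", b"G")}


@dataclass
class DemographicEvent:
    """One backwards-in-time event at ``time`` generations.

    kind = "split": all lineages of ``pop`` move into ``dest``.
    kind = "admixture": each lineage of ``pop`` moves to ``dest`` with
    probability ``proportion`` (the admixture rate ra) else to ``dest2``.
    kind = "size_change": haploid size of ``pop`` becomes ``proportion``
    times its diploid-size scaling (stored as the new diploid N).
    """

    time: float
    kind: str
    pop: str
    dest: str | None = None
    dest2: str | None = None
    proportion: float | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("event times must be strictly positive")
        if self.kind not in ("split", "admixture", "size_change"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "admixture":
            if not (0.0 <= float(self.proportion) <= 1.0):
                raise ValueError("admixture rate must be in [0, 1]")


@dataclass
class ScenarioSpec:
    """A demographic scenario: named populations, diploid effective
    sizes, and an ordered backwards event list ending in a single root."""

    name: str
    populations: list[str]
    sizes: dict[str, float]
    events: list[DemographicEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.populations:
            if p not in self.sizes or self.sizes[p] <= 0:
                raise ValueError(f"population {p!r} needs a positive size")
        self.events = sorted(self.events, key=lambda e: e.time)

    def validate(self, sampled: list[str]) -> None:
        """Check every sampled lineage can reach a single root population."""
        alive = set(sampled)
        for ev in self.events:
            if ev.kind == "split" and ev.pop in alive:
                alive.discard(ev.pop)
                alive.add(ev.dest)
            elif ev.kind == "admixture" and ev.pop in alive:
                alive.discard(ev.pop)
                alive.update([ev.dest, ev.dest2])
        if len(alive) > 1:
            raise ValueError(
                f"scenario {self.name!r}: lineages stranded in {sorted(alive)}"
            )

    def event_arrays(self, ploidy: int = 2):
        """Encode events for the numba kernel; sizes scaled by ploidy."""
        pidx = {p: i for i, p in enumerate(self.populations)}
        ne = len(self.events)
        ev_time = np.empty(ne)
        ev_type = np.zeros(ne, np.int64)
        ev_a = np.zeros(ne, np.int64)
        ev_b = np.zeros(ne, np.int64)
        ev_c = np.zeros(ne, np.int64)
        ev_p = np.zeros(ne)
        for i, ev in enumerate(self.events):
            ev_time[i] = ev.time
            ev_a[i] = pidx[ev.pop]
            if ev.kind == "split":
                ev_type[i] = K.EV_SPLIT
                ev_b[i] = pidx[ev.dest]
            elif ev.kind == "admixture":
                ev_type[i] = K.EV_ADMIX
                ev_b[i] = pidx[ev.dest]
                ev_c[i] = pidx[ev.dest2]
                ev_p[i] = ev.proportion
            else:
                ev_type[i] = K.EV_RESIZE
                ev_p[i] = ploidy * ev.proportion
        sizes = np.array([ploidy * self.sizes[p] for p in self.populations])
        return sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p


@dataclass
class MutationModel:
    """Microsatellite mutation model.

    ``kind`` "smm" is the strict single-step model; "gsm" draws step
    sizes 1 + Geometric(P).  ``rate`` is per locus per generation.
    Allele sizes are confined to ``bounds`` (repeat units, reflecting
    boundaries); 40 contiguous states by default.
    """

    kind: str = "gsm"
    rate: float = 5e-4
    p: float = 0.1
    bounds: tuple[int, int] = (1, 40)

    def __post_init__(self) -> None:
        if self.kind not in ("smm", "gsm"):
            raise ValueError("kind must be 'smm' or 'gsm'")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not (0.0 <= self.p < 1.0):
            raise ValueError("GSM P must be in [0, 1)")
        if self.bounds[0] >= self.bounds[1] or self.bounds[0] < 1:
            raise ValueError("bounds must satisfy 1 <= min < max")

    @property
    def p_eff(self) -> float:
        return 0.0 if self.kind == "smm" else self.p


@dataclass
class Genealogy:
    """A coalescent tree: node i's parent and time (generations).
    Leaves are nodes 0..n-1; the root is the last node."""

    parent: np.ndarray
    time: np.ndarray
    leaf_population: np.ndarray  # population index of each sampled lineage
    populations: list[str]

    @property
    def n_leaves(self) -> int:
        return (self.parent.shape[0] + 1) // 2

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above every non-root node."""
        nonroot = self.parent >= 0
        out = np.zeros_like(self.time)
        out[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return out

    def tmrca(self, i: int, j: int) -> float:
        """Time of the most recent common ancestor of leaves i and j."""
        anc = set()
        v = i
        while v >= 0:
            anc.add(v)
            v = int(self.parent[v])
        v = j
        while v not in anc:
            v = int(self.parent[v])
        return float(self.time[v])


def builtin_scenario(
    hypothesis: int,
    *,
    N_thrace: float,
    N_west: float,
    N_east: float,
    N_central: float,
    N_ancestral: float,
    t1: float,
    t2: float,
    t3: float,
    ra: float,
) -> ScenarioSpec:
    """The three chukar divergence/admixture hypotheses.

    All three share the admixture that creates Central Anatolia from
    West (rate ra) and East (1-ra) at t1.  They differ in split order
    (times are generations before present, backwards):

    1. East and West merge at t2; Thrace joins last at t3.
    2. Thrace, East and West all merge simultaneously at t3.
    3. Thrace merges into West at t2 (their divergence is the most
       recent); East and West merge at t3.

    The post-merge (ancestral) population takes size ``N_ancestral``.
    """
    sizes = {
        "thrace": N_thrace,
        "west": N_west,
        "east": N_east,
        "central": N_central,
    }
    admix = DemographicEvent(t1, "admixture", "central", "west", "east", ra)
    if hypothesis == 1:
        if not (t1 < t2 < t3):
            raise ValueError("hypothesis 1 requires t1 < t2 < t3")
        events = [
            admix,
            DemographicEvent(t2, "split", "east", "west"),
            DemographicEvent(t3, "split", "west", "thrace"),
            DemographicEvent(t3, "size_change", "thrace", proportion=N_ancestral),
        ]
    elif hypothesis == 2:
        if not (t1 < t3):
            raise ValueError("hypothesis 2 requires t1 < t3")
        events = [
            admix,
            DemographicEvent(t3, "split", "east", "west"),
            DemographicEvent(t3, "split", "thrace", "west"),
            DemographicEvent(t3, "size_change", "west", proportion=N_ancestral),
        ]
    elif hypothesis == 3:
        if not (t1 < t2 < t3):
            raise ValueError("hypothesis 3 requires t1 < t2 < t3")
        events = [
            admix,
            DemographicEvent(t2, "split", "thrace", "west"),
            DemographicEvent(t3, "split", "east", "west"),
            DemographicEvent(t3, "size_change", "west", proportion=N_ancestral),
        ]
    else:
        raise ValueError("hypothesis must be 1, 2 or 3")
    return ScenarioSpec(f"hypothesis{hypothesis}", list(SCENARIO_POPS), sizes, events)


def _check_seed(seed) -> int:
    seed = int(seed)
    if not (0 <= seed < 2**32):
        raise ValueError("seed must fit in 32 bits")
    return seed


def simulate_genealogy(
    scenario: ScenarioSpec,
    sample_sizes: dict[str, int],
    seed: int,
    ploidy: int = 2,
) -> Genealogy:
    """Simulate one genealogy of the sampled lineages under a scenario.

    ``sample_sizes`` counts gene copies (lineages) per population.
    """
    sampled = [p for p, m in sample_sizes.items() if m > 0]
    scenario.validate(sampled)
    pidx = {p: i for i, p in enumerate(scenario.populations)}
    pop_of = np.concatenate(
        [np.full(sample_sizes.get(p, 0), pidx[p], np.int64) for p in scenario.populations]
    )
    if pop_of.shape[0] < 2:
        raise ValueError("need at least 2 sampled lineages")
    sizes, *ev = scenario.event_arrays(ploidy)
    parent, ntime, ok = K.sim_genealogy_seeded(_check_seed(seed), pop_of, sizes, *ev)
    if not ok:
        raise ValueError(f"scenario {scenario.name!r}: lineages stranded (no root)")
    return Genealogy(parent, ntime, pop_of, list(scenario.populations))


def mutate_microsat(
    genealogy: Genealogy,
    model: MutationModel,
    root_allele: int,
    seed: int,
) -> np.ndarray:
    """Allele size per leaf after dropping stepwise mutations
    (Poisson(rate x branch length) per branch) on the genealogy."""
    amin, amax = model.bounds
    if not (amin <= root_allele <= amax):
        raise ValueError("root allele outside bounds")
    return np.asarray(
        K.smm_seeded(
            _check_seed(seed),
            genealogy.parent,
            genealogy.time,
            genealogy.n_leaves,
            model.rate,
            model.p_eff,
            amin,
            amax,
            root_allele,
        )
    )


def simulate_msat_dataset(
    scenario: ScenarioSpec,
    models: list[MutationModel] | MutationModel,
    sample_sizes: dict[str, int],
    seed: int,
    n_loci: int | None = None,
    root_allele: int | None = None,
) -> GenotypeMatrix:
    """Simulate a diploid microsatellite dataset: one independent
    genealogy and mutation layer per locus, two gene copies per
    individual.  ``sample_sizes`` counts diploid individuals."""
    if isinstance(models, MutationModel):
        if n_loci is None:
            raise ValueError("give n_loci when a single model is shared")
        models = [models] * n_loci
    L = len(models)
    bounds = models[0].bounds
    if any(m.bounds != bounds for m in models):
        raise ValueError("all loci must share allele bounds")
    if root_allele is None:
        root_allele = (bounds[0] + bounds[1]) // 2
    sampled = [p for p, m in sample_sizes.items() if m > 0]
    scenario.validate(sampled)
    pidx = {p: i for i, p in enumerate(scenario.populations)}
    pops_order = [p for p in scenario.populations if sample_sizes.get(p, 0) > 0]
    pop_of = np.concatenate(
        [np.full(2 * sample_sizes[p], pidx[p], np.int64) for p in pops_order]
    )
    sizes, *ev = scenario.event_arrays(ploidy=2)
    mu = np.array([m.rate for m in models])
    pg = np.array([m.p_eff for m in models])
    alleles, ok = K.sim_msat_seeded(
        _check_seed(seed), pop_of, sizes, *ev, mu, pg, bounds[0], bounds[1], root_allele
    )
    if not ok:
        raise ValueError(f"scenario {scenario.name!r}: lineages stranded (no root)")
    ids, labels = [], []
    for p in pops_order:
        for i in range(sample_sizes[p]):
            ids.append(f"{p}_{i}")
            labels.append(p)
    loci = [f"locus{l + 1}" for l in range(L)]
    return GenotypeMatrix(ids, loci, np.asarray(alleles), labels)


# ---------------------------------------------------------------------------
# mtDNA sequences


def simulate_mtdna(
    n: int,
    *,
    theta: float | None = None,
    expansion: tuple[float, float, float] | None = None,
    L: int = 1014,
    seed: int = 0,
    ts_tv: float = 10.0,
    root_seq: str | None = None,
) -> SequenceAlignment:
    """Simulate a haploid mtDNA alignment of ``n`` sequences.

    Either ``theta`` (constant size, per-sequence scaling theta = 2Nu)
    or ``expansion`` = (tau, theta0, theta1): an instantaneous size
    change at mutational time tau/2 from theta0 (ancient) to theta1
    (present).  Mutations are Poisson on branches and placed on L
    positions (infinite-sites; positions are resampled with replacement
    if segregating sites would exceed L).  Transitions outnumber
    transversions ts_tv : 1, Cyt-b-like.
    """
    if (theta is None) == (expansion is None):
        raise ValueError("give exactly one of theta or expansion")
    rng = np.random.default_rng(seed)
    # scale: per-sequence per-generation mutation rate u = 1, so the
    # haploid size behind theta is theta/2 and tau maps to tau/2 generations
    if expansion is None:
        tau, theta0, theta1 = 0.0, theta, theta
    else:
        tau, theta0, theta1 = expansion
        if min(tau, theta0, theta1) < 0:
            raise ValueError("expansion parameters must be >= 0")
    theta1 = max(theta1, 1e-12)
    theta0 = max(theta0, 1e-12)
    pop_of = np.zeros(n, np.int64)
    sizes = np.array([theta1 / 2.0])
    if tau > 0:
        ev_time = np.array([tau / 2.0])
        ev_type = np.array([K.EV_RESIZE], np.int64)
        ev_a = np.zeros(1, np.int64)
        ev_b = np.zeros(1, np.int64)
        ev_c = np.zeros(1, np.int64)
        ev_p = np.array([theta0 / 2.0])
    else:
        sizes = np.array([theta0 / 2.0])
        ev_time = np.empty(0)
        ev_type = ev_a = ev_b = ev_c = np.empty(0, np.int64)
        ev_p = np.empty(0)
    kseed = int(rng.integers(0, 2**31 - 1))
    parent, ntime, _ = K.sim_genealogy_seeded(
        kseed, pop_of, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p
    )
    blen = np.zeros(2 * n - 1)
    nonroot = parent >= 0
    blen[nonroot] = ntime[parent[nonroot]] - ntime[nonroot]
    total = float(blen.sum())
    n_mut = rng.poisson(total)  # u = 1 per sequence per generation-unit
    if root_seq is None:
        root = rng.choice(_BASES, size=L)
    else:
        if len(root_seq) != L:
            raise ValueError("root_seq length must equal L")
        root = np.frombuffer(root_seq.upper().encode(), dtype="S1").copy()
    seqs = np.tile(root, (2 * n - 1, 1))
    if n_mut > L:
        positions = rng.integers(0, L, size=n_mut)
    else:
        positions = rng.choice(L, size=n_mut, replace=False)
    if n_mut > 0 and total > 0:
        branches = rng.choice(2 * n - 1, size=n_mut, p=blen / total)
        # apply mutations from root downwards: order nodes by decreasing index
        muts_at: dict[int, list[int]] = {}
        for b, pos in zip(branches, positions):
            muts_at.setdefault(int(b), []).append(int(pos))
        for v in range(2 * n - 3, -1, -1):
            seqs[v] = seqs[parent[v]]
            for pos in muts_at.get(v, ()):
                base = seqs[v, pos].tobytes()
                if rng.random() < ts_tv / (ts_tv + 1.0):
                    seqs[v, pos] = np.frombuffer(_TRANSITION[base], dtype="S1")[0]
                else:
                    tv = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
                    seqs[v, pos] = np.frombuffer(tv, dtype="S1")[0]
    else:
        for v in range(2 * n - 3, -1, -1):
            seqs[v] = seqs[parent[v]]
    out = [seqs[i].tobytes().decode() for i in range(n)]
    ids = [f"seq{i}" for i in range(n)]
    return SequenceAlignment(ids, out, ["pop0"] * n)
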