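"""Study-shaped synthetic datasets.

Generates data bundles with the shape of the chukar partridge survey:
16 populations across a Türkiye-like bounding box, per-population
mtDNA alignments (~1014 bp, star-like within-population structure from
sudden expansions), 347 diploid individuals at 13 microsatellite loci
with ~22% missing data, and an optional divergent "clade-B"
contaminant haplogroup injected at a configurable frequency (the
study observed 23 contaminants among 277 sequences, ~8%).

The microsatellite truth is one of the three divergence/admixture
hypotheses; the default is the simultaneous-divergence scenario with
the published posterior point estimates (t3 = 12,600 generations,
t1 = 2,140 generations, ra = 0.5).  The truth record stored with each
bundle is sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .coalescent import MutationModel, builtin_scenario, simulate_msat_dataset, simulate_mtdna
from .io_formats import GenotypeMatrix, PopulationMap, SequenceAlignment
from .popgen_stats import k2p_distance

__all__ = [
    "StudyConfig",
    "StudyBundle",
    "generate_study_like",
    "inject_contamination",
    "contamination_rate",
    "DEFAULT_MTDNA_N",
    "DEFAULT_MSAT_N",
    "DEFAULT_GROUPING",
]

#: Per-population mtDNA sample sizes (populations 1..16).  Populations
#: 7 and 12 were too small for per-population demography in the survey
#: and get small stand-in values.
DEFAULT_MTDNA_N = [16, 9, 20, 22, 22, 20, 5, 20, 20, 20, 20, 3, 20, 21, 20, 19]

#: Per-population diploid microsatellite sample sizes (sum 347).
DEFAULT_MSAT_N = [17, 19, 18, 22, 20, 22, 8, 25, 25, 25, 25, 5, 30, 30, 26, 30]

#: The four ABC clusters over the 16 populations.
DEFAULT_GROUPING = {
    "thrace": ["pop1"],
    "west": ["pop2", "pop3", "pop4", "pop5"],
    "central": ["pop6", "pop7", "pop8", "pop15", "pop16"],
    "east": ["pop9", "pop10", "pop11", "pop12", "pop13", "pop14"],
}

#: Scenario truth defaults: hypothesis 2 at the published posterior
#: point estimates.
DEFAULT_TRUTH = {
    "hypothesis": 2,
    "N_thrace": 2_000.0,
    "N_west": 12_000.0,
    "N_east": 12_000.0,
    "N_central": 10_000.0,
    "N_ancestral": 10_000.0,
    "t1": 2_140.0,
    "t2": 7_000.0,
    "t3": 12_600.0,
    "ra": 0.5,
    "mu": 5e-4,
    "p_gsm": 0.1,
}


@dataclass
class StudyConfig:
    n_populations: int = 16
    mtdna_n: list[int] = field(default_factory=lambda: list(DEFAULT_MTDNA_N))
    msat_n: list[int] = field(default_factory=lambda: list(DEFAULT_MSAT_N))
    n_loci: int = 13
    L: int = 1014
    missing_rate: float = 0.22
    contamination_fraction: float = 23 / 277
    contaminant_divergence: int = 30  # substitutions from the native root
    mtdna_expansion: tuple[float, float, float] = (2.0, 0.5, 20.0)
    truth: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate <= 1 and 0 <= self.contamination_fraction <= 1):
            raise ValueError("rates must be in [0, 1]")
        if len(self.mtdna_n) != self.n_populations or len(self.msat_n) != self.n_populations:
            raise ValueError("per-population sample sizes must match n_populations")
        if min(self.mtdna_n) < 1 or min(self.msat_n) < 1:
            raise ValueError("sample sizes must be positive")


@dataclass
class StudyBundle:
    alignment: SequenceAlignment
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    contaminant_labels: np.ndarray
    truth: dict


def _turkiye_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """n points on a grid spanning a Türkiye-like bounding box
    (lon 26-44 E, lat 36-42 N), west to east."""
    cols = int(np.ceil(n / 2))
    lon = np.linspace(26.5, 43.5, cols)
    pts = []
    for i in range(n):
        c, r = divmod(i, 2)
        pts.append((lon[c], 37.0 + 4.0 * r + 0.3 * ((c * 7919) % 10) / 10))
    arr = np.array(pts)
    return arr[:, 0], arr[:, 1]


def generate_study_like(config: StudyConfig | None = None) -> StudyBundle:
    """Generate one synthetic study bundle under ``config``."""
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    npop = config.n_populations
    pops = [f"pop{i + 1}" for i in range(npop)]

    # mtDNA: per-population sudden expansions sharing one ancestral
    # root haplotype (star-like structure around a common center)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    root_seq = rng.choice(bases, size=config.L).tobytes().decode()
    ids, seqs, labels = [], [], []
    for p, n in zip(pops, config.mtdna_n):
        sub = simulate_mtdna(
            n,
            expansion=config.mtdna_expansion,
            L=config.L,
            seed=int(rng.integers(0, 2**31 - 1)),
            root_seq=root_seq,
        )
        for i, s in enumerate(sub.sequences):
            ids.append(f"{p}_s{i}")
            seqs.append(s)
            labels.append(p)
    aln = SequenceAlignment(ids, seqs, labels)
    aln, contam = inject_contamination(
        aln,
        config.contamination_fraction,
        config.contaminant_divergence,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # microsatellites under the truth scenario, 16 populations mapped
    # onto the four scenario groups
    truth = dict(config.truth)
    scen = builtin_scenario(
        truth["hypothesis"],
        **{k: truth[k] for k in (
            "N_thrace", "N_west", "N_east", "N_central", "N_ancestral",
            "t1", "t2", "t3", "ra",
        )},
    )
    model = MutationModel(kind="gsm", rate=truth["mu"], p=truth["p_gsm"])
    group_of = {p: g for g, ps in DEFAULT_GROUPING.items() for p in ps}
    cluster_sizes: dict[str, int] = {}
    for p, n in zip(pops, config.msat_n):
        g = group_of.get(p, "central")
        cluster_sizes[g] = cluster_sizes.get(g, 0) + n
    G = simulate_msat_dataset(
        scen, model, cluster_sizes,
        seed=int(rng.integers(0, 2**31 - 1)), n_loci=config.n_loci,
    )
    # relabel cluster individuals back to their 16 populations
    new_labels = []
    counters = {g: iter([p for p in pops if group_of.get(p, "central") == g
                         for _ in range(config.msat_n[pops.index(p)])])
                for g in cluster_sizes}
    for lab in G.pop_labels:
        new_labels.append(next(counters[lab]))
    alleles = G.alleles.copy()
    if config.missing_rate > 0:
        mask = rng.random((G.n, G.n_loci)) < config.missing_rate
        alleles[mask] = 0
    G = GenotypeMatrix(G.individual_ids, G.locus_names, alleles, new_labels)

    lon, lat = _turkiye_grid(npop)
    popmap = PopulationMap(pops, pops, lon, lat)
    truth_record = {
        "config": {**asdict(config), "truth": truth},
        "n_contaminants": int(contam.sum()),
    }
    return StudyBundle(aln, G, popmap, contam, truth_record)


def inject_contamination(
    aln: SequenceAlignment,
    fraction: float,
    divergence: int,
    seed: int = 0,
) -> tuple[SequenceAlignment, np.ndarray]:
    """Replace round(fraction * n) sequences by descendants of a
    divergent contaminant haplogroup.

    The contaminant root sits ``divergence`` substitutions from the
    (majority-rule) native root; contaminants carry a little private
    variation on top.  Returns the modified alignment and a boolean
    truth-label vector.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    n = aln.n
    n_cont = int(round(fraction * n))
    labels = np.zeros(n, bool)
    if n_cont == 0:
        return aln, labels
    rng = np.random.default_rng(seed)
    M = aln.matrix().copy()
    # native consensus as root proxy
    root = []
    for col in M.T:
        vals, counts = np.unique(col, return_counts=True)
        root.append(vals[np.argmax(counts)])
    root = np.array(root)
    L = aln.L
    pos = rng.choice(L, size=min(divergence, L), replace=False)
    cont_root = root.copy()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for p in pos:
        alt = bases[bases != cont_root[p]]
        cont_root[p] = alt[rng.integers(0, len(alt))]
    idx = rng.choice(n, size=n_cont, replace=False)
    for i in idx:
        s = cont_root.copy()
        # private variation: ~1 extra substitution on average
        for p in rng.choice(L, size=rng.poisson(1.0), replace=False):
            alt = bases[bases != s[p]]
            s[p] = alt[rng.integers(0, len(alt))]
        M[i] = s
        labels[i] = True
    seqs = [M[i].tobytes().decode() for i in range(n)]
    out = SequenceAlignment(list(aln.sample_ids), seqs, list(aln.pop_labels))
    return out, labels


def contamination_rate(labels: np.ndarray) -> tuple[int, float]:
    """(rounded percent for display, unrounded percent)."""
    labels = np.asarray(labels, bool)
    if labels.size == 0:
        raise ValueError("empty label vector")
    pct = 100.0 * labels.sum() / labels.size
    return int(round(pct)), float(pct)


def mean_cross_distance(aln: SequenceAlignment, labels: np.ndarray) -> float:
    """Mean native-contaminant K2P distance (diagnostic for the
    injected divergence)."""
    nat = [s for s, c in zip(aln.sequences, labels) if not c]
    con = [s for s, c in zip(aln.sequences, labels) if c]
    if not nat or not con:
        raise ValueError("need both native and contaminant sequences")
    ds = [k2p_distance(a, b) for a in nat[:20] for b in con[:20]]
    return float(np.mean(ds))
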