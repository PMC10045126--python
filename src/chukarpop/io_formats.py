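"""Readers/writers for the pipeline's exchange formats.

Three formats are supported: FASTA for aligned mtDNA haplotype data
(via Biopython), the GenePop dialect for diploid microsatellite
genotypes, and a small CSV table mapping population ids to names and
decimal-degree coordinates.  Each reader validates its input into one
of the domain containers below; writers round-trip exactly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceAlignment",
    "GenotypeMatrix",
    "PopulationMap",
    "AlignmentError",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_genepop",
    "write_genepop",
    "read_popmap",
    "write_popmap",
]

_VALID_BASES = set("ACGTN-")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (e.g. ragged lengths)."""


class FormatError(ValueError):
    """A file violates its format contract."""


@dataclass
class SequenceAlignment:
    """Aligned sequences with per-sample population labels.

    ``sequences`` are equal-length uppercase strings over {A,C,G,T,N,-}.
    Gaps and Ns are retained here; distance computations downstream
    exclude them pairwise.
    """

    sample_ids: list[str]
    sequences: list[str]
    pop_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.sequences) != n or len(self.pop_labels) != n:
            raise AlignmentError("sample_ids, sequences and pop_labels must align")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids")
        self.sequences = [s.upper() for s in self.sequences]
        if n:
            L = len(self.sequences[0])
            for s in self.sequences:
                if len(s) != L:
                    raise AlignmentError("ragged sequence lengths")
                bad = set(s) - _VALID_BASES
                if bad:
                    raise FormatError(f"invalid characters in sequence: {sorted(bad)}")
        if any(not p for p in self.pop_labels):
            raise FormatError("empty population label")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def L(self) -> int:
        """Alignment length in bp."""
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def populations(self) -> list[str]:
        """Population names in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def subset(self, idx) -> "SequenceAlignment":
        idx = list(idx)
        return SequenceAlignment(
            [self.sample_ids[i] for i in idx],
            [self.sequences[i] for i in idx],
            [self.pop_labels[i] for i in idx],
        )

    def by_population(self) -> dict[str, "SequenceAlignment"]:
        return {
            p: self.subset([i for i, q in enumerate(self.pop_labels) if q == p])
            for p in self.populations
        }

    def matrix(self) -> np.ndarray:
        """Alignment as a byte matrix (n, L) for vectorized comparisons."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.L)


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite genotypes: allele repeat sizes per
    individual x locus, with ``(0, 0)`` encoding a missing genotype.

    Allele pairs are unordered and stored sorted.
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray  # (n, L, 2) non-negative int
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.alleles.shape != (n, L, 2):
            raise FormatError(f"allele array must be ({n}, {L}, 2)")
        if len(self.pop_labels) != n:
            raise FormatError("pop_labels must match individuals")
        if len(set(self.locus_names)) != L:
            raise FormatError("duplicate locus names")
        if (self.alleles < 0).any():
            raise FormatError("negative allele size")
        half_missing = (self.alleles == 0).sum(axis=2) == 1
        if half_missing.any():
            raise FormatError("missing data must be encoded as (0, 0) only")
        self.alleles = np.sort(self.alleles, axis=2)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing genotypes."""
        return (self.alleles == 0).all(axis=2)

    def missing_rate(self) -> float:
        return float(self.missing_mask.mean())

    def group_indices(self, grouping: dict[str, list[str]] | None = None) -> dict[str, np.ndarray]:
        """Row indices per population, or per named cluster of populations."""
        labels = np.asarray(self.pop_labels)
        if grouping is None:
            return {p: np.flatnonzero(labels == p) for p in self.populations}
        return {
            g: np.flatnonzero(np.isin(labels, pops)) for g, pops in grouping.items()
        }


@dataclass
class PopulationMap:
    """Population id -> (name, longitude, latitude), decimal degrees."""

    ids: list[str] = field(default_factory=list)
    names: list[str] = field(default_factory=list)
    lon: np.ndarray = field(default_factory=lambda: np.empty(0))
    lat: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        k = len(self.ids)
        if len(self.names) != k or len(self.lon) != k or len(self.lat) != k:
            raise FormatError("popmap columns must align")
        if len(set(self.ids)) != k:
            raise FormatError("duplicate population ids")
        if k and not (np.isfinite(self.lon).all() and np.isfinite(self.lat).all()):
            raise FormatError("non-finite coordinate")
        if k and ((np.abs(self.lat) > 90).any() or (np.abs(self.lon) > 180).any()):
            raise FormatError("coordinate out of range")

    def __len__(self) -> int:
        return len(self.ids)

    def coords(self) -> np.ndarray:
        """(k, 2) array of (lon, lat)."""
        return np.column_stack([self.lon, self.lat])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, pop_labels: list[str] | None = None) -> SequenceAlignment:
    """Read an aligned FASTA file.

    Population labels default to the substring after the last ``|`` of
    each record id (a common convention for popgen FASTA exports) or
    ``"pop0"`` when the id carries no label.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate FASTA record ids")
    seqs = [str(r.seq).upper() for r in records]
    if pop_labels is None:
        pop_labels = [i.rsplit("|", 1)[1] if "|" in i else "pop0" for i in ids]
        ids = [i.rsplit("|", 1)[0] if "|" in i else i for i in ids]
    return SequenceAlignment(ids, seqs, pop_labels)


def write_fasta(aln: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{i}|{p}", description="")
        for i, s, p in zip(aln.sample_ids, aln.sequences, aln.pop_labels)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GenePop (3-digit diploid dialect)


def read_genepop(path) -> GenotypeMatrix:
    """Read a GenePop file in the 3-digit diploid dialect.

    ``000000`` encodes a missing genotype.  ``Pop`` lines delimit
    populations; population labels are ``pop1``, ``pop2``, ... in order
    of appearance (GenePop itself names populations only implicitly).
    """
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh]
    if not lines:
        raise FormatError("empty GenePop file")
    # line 0: title; then locus names until first Pop
    i = 1
    loci: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # loci may be one per line or comma-separated
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise FormatError("no 'Pop' separator found")
    ids, pops, rows = [], [], []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            if i >= len(lines) or lines[i].strip().lower() == "pop":
                warnings.warn(f"empty Pop block #{pop_idx} in {path}")
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise FormatError(f"genotype line without id separator: {line!r}")
        ind_id, rest = line.split(",", 1)
        fields = rest.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"{ind_id.strip()}: expected {len(loci)} loci, got {len(fields)}"
            )
        row = []
        for f in fields:
            if len(f) != 6 or not f.isdigit():
                raise FormatError(
                    f"{ind_id.strip()}: allele string {f!r} is not 3-digit diploid "
                    "(6 digits); 2-digit GenePop coding is not supported"
                )
            row.append((int(f[:3]), int(f[3:])))
        ids.append(ind_id.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    return GenotypeMatrix(ids, loci, np.array(rows, dtype=np.int64), pops)


def write_genepop(G: GenotypeMatrix, path, title: str = "chukarpop export") -> None:
    buf = io.StringIO()
    buf.write(title + "\n")
    for loc in G.locus_names:
        buf.write(loc + "\n")
    for p in G.populations:
        buf.write("Pop\n")
        for i in np.flatnonzero(np.asarray(G.pop_labels) == p):
            geno = " ".join(
                f"{a:03d}{b:03d}" for a, b in G.alleles[i]
            )
            buf.write(f"{G.individual_ids[i]}, {geno}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Population map CSV


def read_popmap(path) -> PopulationMap:
    try:
        df = pd.read_csv(path, dtype={"id": str, "name": str})
    except pd.errors.EmptyDataError:
        return PopulationMap()
    if df.empty:
        return PopulationMap()
    required = {"id", "name", "lon", "lat"}
    if not required.issubset(df.columns):
        raise FormatError(f"popmap needs columns {sorted(required)}")
    try:
        lon = df["lon"].astype(float).to_numpy()
        lat = df["lat"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"unparsable coordinate in {path}: {exc}") from exc
    return PopulationMap(list(df["id"]), list(df["name"]), lon, lat)


def write_popmap(pm: PopulationMap, path) -> None:
    pd.DataFrame(
        {"id": pm.ids, "name": pm.names, "lon": pm.lon, "lat": pm.lat}
    ).to_csv(path, index=False)
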