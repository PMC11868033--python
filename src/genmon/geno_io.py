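"""Genotype containers and interchange-format I/O.

The central container is :class:`GenotypeMatrix`: diploid, biallelic SNP
genotypes stored as reference-allele dosage (0, 1, 2) with an explicit
missing sentinel, plus per-individual population labels and optional
sampling metadata.  Readers exist for the GENEPOP dialect (2- and 3-digit
allele codes), a STRUCTURE-style two-row text format (read-only), and a
plain CSV dosage table; a GENEPOP writer closes the round trip.

Allele frequencies per group are collected in :class:`AlleleFreqTable`,
the "P matrix" consumed by the ancestry and divergence modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an untyped genotype.  Never 0 — dosage 0 is a real homozygote.
MISSING: int = -9

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFreqTable",
    "read_genepop",
    "write_genepop",
    "read_csv_genotypes",
    "write_csv_genotypes",
    "read_structure",
    "allele_frequencies",
]


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid dosage matrix with sample labels.

    Parameters
    ----------
    individuals
        Individual identifiers, length ``n_ind``.
    loci
        Unique locus identifiers, length ``n_loci``.
    dosage
        ``(n_ind, n_loci)`` integer array counting copies of the designated
        reference allele; entries in ``{0, 1, 2, MISSING}``.
    pop_label
        Population / locality label per individual (non-empty).
    year
        Optional sampling year per individual.
    meta
        Optional per-individual metadata table (distance_km, maturity_flag,
        age, sex, ...), indexed like ``individuals``.
    """

    individuals: list[str]
    loci: list[str]
    dosage: np.ndarray
    pop_label: list[str]
    year: list[int] | None = None
    meta: pd.DataFrame | None = None
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-dimensional")
        n_ind, n_loci = self.dosage.shape
        if n_ind < 1 or n_loci < 1:
            raise ValueError("need at least one individual and one locus")
        if len(self.individuals) != n_ind:
            raise ValueError("individuals length mismatch")
        if len(self.loci) != n_loci:
            raise ValueError("loci length mismatch")
        if len(set(self.loci)) != n_loci:
            raise ValueError("locus ids must be unique")
        if len(self.pop_label) != n_ind or any(not p for p in self.pop_label):
            raise ValueError("pop_label must be non-empty for every individual")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            bad = self.dosage[~ok].ravel()[0]
            raise ValueError(f"invalid dosage value {bad}; allowed 0/1/2/MISSING")

    # -- convenience -------------------------------------------------------
    @property
    def n_ind(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def pops(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_label:
            seen.setdefault(p)
        return list(seen)

    def typed(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.dosage != MISSING

    def subset(self, rows: np.ndarray | list[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given individual indices (in order)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in rows],
            loci=list(self.loci),
            dosage=self.dosage[rows],
            pop_label=[self.pop_label[i] for i in rows],
            year=None if self.year is None else [self.year[i] for i in rows],
            meta=None if self.meta is None else self.meta.iloc[rows].reset_index(drop=True),
            truth=None if self.truth is None else self.truth.iloc[rows].reset_index(drop=True),
        )

    def by_pop(self, label: str) -> "GenotypeMatrix":
        rows = [i for i, p in enumerate(self.pop_label) if p == label]
        if not rows:
            raise KeyError(f"unknown population label {label!r}")
        return self.subset(rows)


@dataclass
class AlleleFreqTable:
    """Per-population, per-locus reference-allele frequency with copy counts.

    ``freq[i, l]`` is defined only where ``copies[i, l] > 0``; undefined
    cells hold ``nan``.
    """

    pops: list[str]
    loci: list[str]
    freq: np.ndarray
    copies: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.copies = np.asarray(self.copies, dtype=int)
        if self.freq.shape != (len(self.pops), len(self.loci)):
            raise ValueError("freq shape mismatch")
        if self.copies.shape != self.freq.shape:
            raise ValueError("copies shape mismatch")
        if (self.copies < 0).any():
            raise ValueError("copies must be >= 0")
        defined = self.copies > 0
        f = self.freq[defined]
        if f.size and ((f < 0) | (f > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if np.isfinite(self.freq[~defined]).any():
            self.freq = self.freq.copy()
            self.freq[~defined] = np.nan

    def row(self, pop: str) -> np.ndarray:
        try:
            return self.freq[self.pops.index(pop)]
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.pops, columns=self.loci)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def _parse_genepop_token(token: str, width: int) -> tuple[str, str]:
    if len(token) != 2 * width or not token.isdigit():
        raise ValueError(f"malformed genotype token {token!r}")
    return token[:width], token[width:]


def read_genepop(path) -> GenotypeMatrix:
    """Read a GENEPOP file into a :class:`GenotypeMatrix`.

    Biallelic loci are mapped to dosage of the lexicographically smaller
    allele code (the designated reference).  The all-zero code (``00`` /
    ``000``) denotes a missing genotype.  Population blocks (``POP`` lines)
    become ``pop_label`` values named ``P1, P2, ...`` unless the first
    individual id in the block is informative, in which case that id is used
    as the block label (the common GENEPOP convention).

    Raises
    ------
    ValueError
        On a locus with more than two alleles, or a malformed individual
        line (reported with its line number).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty GENEPOP file")
    # title line is lines[0]; locus names until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise ValueError("no POP separator found")
    n_loci = len(loci)

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    pop_index = 0
    block_first_id: str | None = None
    width: int | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().upper() == "POP":
            pop_index += 1
            block_first_id = None
            continue
        if "," not in raw:
            raise ValueError(f"line {lineno + 1}: missing ',' separator")
        ind_id, geno = raw.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno.split()
        if len(tokens) != n_loci:
            raise ValueError(
                f"line {lineno + 1}: expected {n_loci} genotypes, got {len(tokens)}"
            )
        if width is None:
            if len(tokens[0]) not in (4, 6):
                raise ValueError(
                    f"line {lineno + 1}: genotype token {tokens[0]!r} is not 4 or 6 digits"
                )
            width = len(tokens[0]) // 2
        try:
            pair = [_parse_genepop_token(t, width) for t in tokens]
        except ValueError as e:
            raise ValueError(f"line {lineno + 1}: {e}") from None
        if block_first_id is None:
            block_first_id = ind_id
        ids.append(ind_id)
        pops.append(f"P{pop_index}")
        rows.append(pair)

    if not rows:
        raise ValueError("no individuals found")

    zero = "0" * (width or 2)
    # collect observed alleles per locus
    dosage = np.full((len(rows), n_loci), MISSING, dtype=np.int16)
    for l in range(n_loci):
        alleles = sorted(
            {a for row in rows for a in row[l] if a != zero}
        )
        if len(alleles) > 2:
            raise ValueError(
                f"locus {loci[l]!r} has {len(alleles)} alleles; biallelic data required"
            )
        ref = alleles[0] if alleles else None
        for r, row in enumerate(rows):
            a1, a2 = row[l]
            if a1 == zero or a2 == zero:
                continue
            dosage[r, l] = int(a1 == ref) + int(a2 == ref)
    return GenotypeMatrix(ids, loci, dosage, pops)


def write_genepop(gm: GenotypeMatrix, path, title: str = "genmon export") -> None:
    """Write GENEPOP with reference allele coded 01, alternate 02, missing 0000."""
    code = {2: "0101", 1: "0102", 0: "0202", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gm.loci:
            fh.write(locus + "\n")
        last = None
        for i in range(gm.n_ind):
            if gm.pop_label[i] != last:
                fh.write("POP\n")
                last = gm.pop_label[i]
            tokens = " ".join(code[int(d)] for d in gm.dosage[i])
            fh.write(f"{gm.individuals[i]} , {tokens}\n")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv_genotypes(path) -> GenotypeMatrix:
    """Read the CSV dosage layout: header ``id,pop,year,<locus ids...>``.

    Cells are 0/1/2 reference-allele dosages or ``NA`` for missing.
    """
    df = pd.read_csv(path, dtype={"id": str, "pop": str})
    required = ["id", "pop", "year"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"CSV header must start with {required}")
    loci = list(df.columns[3:])
    if not loci:
        raise ValueError("no locus columns")
    raw = df[loci].to_numpy()
    dosage = np.full(raw.shape, MISSING, dtype=np.int16)
    for (r, c), v in np.ndenumerate(raw):
        if pd.isna(v) or (isinstance(v, str) and v.strip().upper() == "NA"):
            continue
        iv = int(v)
        if iv not in (0, 1, 2):
            raise ValueError(f"dosage {v!r} outside {{0,1,2,NA}} at row {r}, locus {loci[c]}")
        dosage[r, c] = iv
    years = None
    if df["year"].notna().any():
        years = [int(y) if pd.notna(y) else -1 for y in df["year"]]
    return GenotypeMatrix(list(df["id"]), loci, dosage, list(df["pop"]), year=years)


def write_csv_genotypes(gm: GenotypeMatrix, path) -> None:
    body = pd.DataFrame(gm.dosage.astype(object), columns=gm.loci)
    body = body.mask(gm.dosage == MISSING, "NA")
    head = pd.DataFrame(
        {
            "id": gm.individuals,
            "pop": gm.pop_label,
            "year": gm.year if gm.year is not None else [""] * gm.n_ind,
        }
    )
    pd.concat([head, body], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# STRUCTURE two-row (read-only)
# ---------------------------------------------------------------------------

def read_structure(path) -> GenotypeMatrix:
    """Read STRUCTURE-style two-row text: header of locus names, then two
    lines per individual ``id pop a1 a2 ...`` with one allele per locus per
    row; ``-9`` denotes a missing allele.  Reference allele per locus is the
    numerically smaller observed code.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    loci = lines[0].split()
    n_loci = len(loci)
    body = [ln.split() for ln in lines[1:]]
    if len(body) % 2:
        raise ValueError("two-row format requires an even number of data lines")
    ids, pops = [], []
    allele_rows = []
    for a, b in zip(body[::2], body[1::2]):
        if a[0] != b[0]:
            raise ValueError(f"row pair mismatch: {a[0]} vs {b[0]}")
        if len(a) != n_loci + 2 or len(b) != n_loci + 2:
            raise ValueError(f"individual {a[0]}: wrong column count")
        ids.append(a[0])
        pops.append(a[1])
        allele_rows.append((np.array(a[2:], int), np.array(b[2:], int)))
    dosage = np.full((len(ids), n_loci), MISSING, dtype=np.int16)
    for l in range(n_loci):
        obs = sorted(
            {int(r[k][l]) for r in allele_rows for k in (0, 1)} - {-9}
        )
        if len(obs) > 2:
            raise ValueError(f"locus {loci[l]!r} has >2 alleles")
        ref = obs[0] if obs else None
        for i, (r1, r2) in enumerate(allele_rows):
            if r1[l] == -9 or r2[l] == -9:
                continue
            dosage[i, l] = int(r1[l] == ref) + int(r2[l] == ref)
    return GenotypeMatrix(ids, loci, dosage, pops)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    gm: GenotypeMatrix, group_by: str | list[str] | None = None
) -> AlleleFreqTable:
    """Reference-allele frequencies per group x locus.

    ``freq = (sum of dosages) / (2 x typed individuals)`` within each group,
    complete-case per locus.  Cells with zero typed copies are undefined
    (``nan`` with ``copies == 0``).

    Parameters
    ----------
    gm
        Genotype matrix.
    group_by
        ``None`` to group by ``pop_label`` (default); or an explicit list of
        per-individual group labels of length ``n_ind``.
    """
    if group_by is None:
        labels = gm.pop_label
    elif isinstance(group_by, str):
        if group_by == "pop":
            labels = gm.pop_label
        else:
            raise KeyError(f"unknown grouping {group_by!r}")
    else:
        if len(group_by) != gm.n_ind:
            raise ValueError("group_by length mismatch")
        labels = list(group_by)
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        groups.setdefault(g, []).append(i)
    pops = list(groups)
    freq = np.full((len(pops), gm.n_loci), np.nan)
    copies = np.zeros((len(pops), gm.n_loci), dtype=int)
    for gi, g in enumerate(pops):
        d = gm.dosage[groups[g]]
        typed = d != MISSING
        n_copies = 2 * typed.sum(axis=0)
        total = np.where(typed, d, 0).sum(axis=0)
        copies[gi] = n_copies
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[gi] = np.where(n_copies > 0, total / np.maximum(n_copies, 1), np.nan)
    return AlleleFreqTable(pops, list(gm.loci), freq, copies)
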