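"""Site-level filters: orthology, polymorphism, Ti/Tv, assay validation and
parsimonious imputation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix import Call, HaplotypeMatrix, PURINES, PYRIMIDINES, VALID_BASES

GAP_CHARS = frozenset("-.")
MISSING_CHARS = frozenset("NX?")


@dataclass(frozen=True)
class SubstitutionRecord:
    site_index: int
    allele_a: str
    allele_b: str
    kind: str  # TRANSITION | TRANSVERSION
    scope: str = "INTRASPECIFIC"


def substitution_kind(a: str, b: str) -> str:
    """TRANSITION for purine<->purine or pyrimidine<->pyrimidine changes,
    TRANSVERSION otherwise."""
    a, b = a.upper(), b.upper()
    for x in (a, b):
        if x not in VALID_BASES:
            raise ValueError(f"allele {x!r} is not one of A/C/G/T")
    if a == b:
        raise ValueError(f"not a substitution: {a} -> {b}")
    same_class = ({a, b} <= PURINES) or ({a, b} <= PYRIMIDINES)
    return "TRANSITION" if same_class else "TRANSVERSION"


def classify_titv(pairs: Sequence[tuple[str, str]]) -> tuple[int, int]:
    """Count (transitions, transversions) over bi-allelic allele pairs."""
    ti = tv = 0
    for a, b in pairs:
        if substitution_kind(a, b) == "TRANSITION":
            ti += 1
        else:
            tv += 1
    return ti, tv


def classify_titv_matrix(m: HaplotypeMatrix) -> tuple[int, int]:
    return classify_titv(
        [(s.ancestral_allele, s.derived_allele) for s in m.sites]
    )


# ---------------------------------------------------------------------------
# orthologous / variable site sets
# ---------------------------------------------------------------------------

def filter_sites(
    alignment: "Mapping[str, str] | HaplotypeMatrix",
    ingroup: Sequence[str] | None = None,
) -> tuple[list[int], list[int]]:
    """Split alignment columns into orthologous and ingroup-variable sets.

    ``alignment`` is either a taxon -> aligned-sequence mapping (gaps ``-``,
    missing ``N``/``X``/``?``) or a :class:`HaplotypeMatrix` (which has no
    gaps; calls are compared as ancestral/derived states).  The orthologous
    set drops every column with a gap in any taxon; the variable set is the
    subset of orthologous columns polymorphic within ``ingroup`` (default:
    all taxa / all sequenced samples).  Both are returned in site order, so
    ``variable ⊆ orthologous``.
    """
    if isinstance(alignment, HaplotypeMatrix):
        return _filter_sites_matrix(alignment, ingroup)
    if not alignment:
        raise ValueError("empty alignment")
    taxa = list(alignment)
    lengths = {len(alignment[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {lengths}")
    (n_sites,) = lengths
    if n_sites == 0:
        raise ValueError("empty alignment")
    ingroup = list(ingroup) if ingroup is not None else taxa
    for t in ingroup:
        if t not in alignment:
            raise KeyError(f"ingroup taxon {t!r} not in alignment")
    orthologous: list[int] = []
    variable: list[int] = []
    for j in range(n_sites):
        column = {t: alignment[t][j].upper() for t in taxa}
        if any(c in GAP_CHARS for c in column.values()):
            continue
        orthologous.append(j)
        states = {
            column[t] for t in ingroup if column[t] not in MISSING_CHARS
        }
        if len(states) > 1:
            variable.append(j)
    return orthologous, variable


def _filter_sites_matrix(
    m: HaplotypeMatrix, ingroup: Sequence[str] | None
) -> tuple[list[int], list[int]]:
    if m.n_sites == 0 or m.n_samples == 0:
        raise ValueError("empty matrix")
    if ingroup is None:
        ingroup = [s.identifier for s in m.samples if s.sequenced]
    rows = np.array([m.sample_index(s) for s in ingroup])
    orthologous = list(range(m.n_sites))
    variable = []
    for j in orthologous:
        col = m.calls[rows, j]
        states = set(col[col != Call.MISSING].tolist())
        if len(states) > 1:
            variable.append(j)
    return orthologous, variable


# ---------------------------------------------------------------------------
# male-specificity (assay validation)
# ---------------------------------------------------------------------------

@dataclass
class AssayValidationTable:
    """Genotyping outcomes for candidate Y loci in males and females.

    Calls are genotype strings, with None for no amplification.  Female
    amplification at a putative Y locus marks non-specific primers.
    """

    loci: list[str]
    female_calls: dict[str, list[str | None]]
    male_calls: dict[str, list[str | None]] = field(default_factory=dict)
    male_expected: dict[str, list[str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_females = {len(v) for v in self.female_calls.values()}
        if len(n_females) > 1:
            raise ValueError("female call lists have inconsistent lengths")
        for locus in self.loci:
            if locus not in self.female_calls:
                raise ValueError(f"no female calls for locus {locus}")

    @property
    def n_females(self) -> int:
        return len(next(iter(self.female_calls.values())))


@dataclass
class AssayValidationResult:
    validated_loci: list[str]
    dropped_loci: list[str]
    false_positive_rate: float
    male_concordance: float | None


def female_specificity_filter(
    table: AssayValidationTable, locus_drop_fraction: float = 0.25
) -> AssayValidationResult:
    """Retain loci that amplify male-specifically.

    A locus is dropped when it amplifies in more than ``locus_drop_fraction``
    of females (consistent amplification implies the primers are not
    Y-specific).  Sporadic female positives among the retained loci are
    tolerated and summarised as a per-call false-positive rate:
    female-positive calls / (retained loci x females).  Male genotype
    concordance against prior sequence-based calls is reported when both are
    supplied.
    """
    n_females = table.n_females
    if n_females < 1:
        raise ValueError("at least one female is required for validation")
    validated, dropped = [], []
    for locus in table.loci:
        n_amp = sum(c is not None for c in table.female_calls[locus])
        (dropped if n_amp / n_females > locus_drop_fraction else validated
         ).append(locus)
    fp = sum(
        c is not None
        for locus in validated
        for c in table.female_calls[locus]
    )
    fp_rate = fp / (len(validated) * n_females) if validated else 0.0

    concordance = None
    if table.male_calls and table.male_expected:
        match = total = 0
        for locus in validated:
            calls = table.male_calls.get(locus, [])
            expect = table.male_expected.get(locus, [])
            for c, e in zip(calls, expect):
                if c is not None and e is not None:
                    total += 1
                    match += c == e
        concordance = match / total if total else None
    return AssayValidationResult(
        validated_loci=validated,
        dropped_loci=dropped,
        false_positive_rate=fp_rate,
        male_concordance=concordance,
    )


# ---------------------------------------------------------------------------
# parsimonious imputation
# ---------------------------------------------------------------------------

def impute_missing(m: HaplotypeMatrix) -> HaplotypeMatrix:
    """Fill missing calls from otherwise identical complete haplotypes.

    A missing call is imputed only when every complete row that matches the
    focal row at all of its non-missing sites carries the same allele at the
    missing site; any disagreement, or no matching complete row, leaves the
    call missing.  Non-missing calls are never altered, and the operation is
    idempotent (imputed rows are still compared against original complete
    rows only).
    """
    calls = m.calls.copy()
    complete = [i for i in range(m.n_samples)
                if not (m.calls[i] == Call.MISSING).any()]
    for i in range(m.n_samples):
        row = m.calls[i]
        missing = np.flatnonzero(row == Call.MISSING)
        if missing.size == 0:
            continue
        known = row != Call.MISSING
        matches = [
            c for c in complete
            if np.array_equal(m.calls[c][known], row[known])
        ]
        if not matches:
            continue
        for j in missing:
            alleles = {int(m.calls[c][j]) for c in matches}
            if len(alleles) == 1:
                calls[i, j] = alleles.pop()
    return m.with_calls(calls)
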