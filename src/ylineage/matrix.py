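"""Core containers for haplotype SNP panels.

A :class:`HaplotypeMatrix` holds single-character calls for a set of male
samples at a panel of bi-allelic Y-chromosome sites, relative to an ancestral
reference state inferred from outgroups.  Calls are stored as integer codes
(ancestral / derived / missing) rather than bases; the per-site allele pair
lives in :class:`SiteDef`.  Because the male-specific Y does not recombine,
the sites can be treated as one linked haplotype regardless of their physical
position.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

VALID_BASES = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class Call(enum.IntEnum):
    """Per-sample per-site call relative to the ancestral state."""

    ANCESTRAL = 0
    DERIVED = 1
    MISSING = -1


@dataclass(frozen=True)
class SiteDef:
    """Definition of one bi-allelic Y site.

    Parameters
    ----------
    locus_id
        Unique label, conventionally ``<fragment>_<position><alleles>``
        (e.g. ``G_343GC``).
    ancestral_allele, derived_allele
        The two observed bases; the ancestral state is the one shared with
        the outgroup consensus.
    assayed
        True for loci with a validated male-specific genotyping assay.
    source_fragment
        Reference fragment the site was discovered on.
    position_on_reference
        1-based position on the reference fragment, or None if unknown.
    """

    locus_id: str
    ancestral_allele: str
    derived_allele: str
    assayed: bool = False
    source_fragment: str = ""
    position_on_reference: int | None = None

    def __post_init__(self) -> None:
        if self.ancestral_allele not in VALID_BASES:
            raise ValueError(
                f"{self.locus_id}: ancestral allele {self.ancestral_allele!r} "
                "is not one of A/C/G/T"
            )
        if self.derived_allele not in VALID_BASES:
            raise ValueError(
                f"{self.locus_id}: derived allele {self.derived_allele!r} "
                "is not one of A/C/G/T"
            )
        if self.ancestral_allele == self.derived_allele:
            raise ValueError(
                f"{self.locus_id}: ancestral and derived alleles are identical"
            )

    @property
    def is_transition(self) -> bool:
        pair = {self.ancestral_allele, self.derived_allele}
        return pair == set("AG") or pair == set("CT")


@dataclass(frozen=True)
class SampleDef:
    """One male sample: identifier, sampling population and data provenance."""

    identifier: str
    population: str = ""
    sequenced: bool = True
    genotyped: bool = False


class HaplotypeMatrix:
    """Samples x sites call matrix with an implicit all-ancestral root row.

    ``calls`` is an int8 array with values from :class:`Call`; rows follow
    ``samples`` order, columns follow ``sites`` order.
    """

    def __init__(
        self,
        sites: Sequence[SiteDef],
        samples: Sequence[SampleDef],
        calls: np.ndarray,
        metadata: dict | None = None,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(calls, [Call.ANCESTRAL, Call.DERIVED, Call.MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call code {calls[i, j]} for sample "
                f"{self.samples[i].identifier} at locus {self.sites[j].locus_id}"
            )
        ids = [s.identifier for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample identifiers are not unique")
        loci = [s.locus_id for s in self.sites]
        if len(set(loci)) != len(loci):
            raise ValueError("locus ids are not unique")
        self.calls = calls
        self.metadata = dict(metadata or {})

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.identifier for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [s.locus_id for s in self.sites]

    @property
    def ancestral_row(self) -> np.ndarray:
        """The all-ancestral reference state vector."""
        return np.zeros(self.n_sites, dtype=np.int8)

    def sample_index(self, identifier: str) -> int:
        try:
            return self.sample_ids.index(identifier)
        except ValueError:
            raise KeyError(f"unknown sample {identifier!r}") from None

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus {locus_id!r}") from None

    def row(self, identifier: str) -> np.ndarray:
        return self.calls[self.sample_index(identifier)]

    def has_missing(self) -> bool:
        return bool((self.calls == Call.MISSING).any())

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        samples: Iterable[str] | None = None,
        sites: Iterable[str] | None = None,
    ) -> "HaplotypeMatrix":
        """Return a new matrix restricted to the given samples/loci (by id)."""
        if samples is None:
            ridx = list(range(self.n_samples))
        else:
            ridx = [self.sample_index(s) for s in samples]
        if sites is None:
            cidx = list(range(self.n_sites))
        else:
            cidx = [self.locus_index(s) for s in sites]
        return HaplotypeMatrix(
            [self.sites[j] for j in cidx],
            [self.samples[i] for i in ridx],
            self.calls[np.ix_(ridx, cidx)],
            metadata=dict(self.metadata),
        )

    def sequenced_subset(self) -> "HaplotypeMatrix":
        return self.subset(
            samples=[s.identifier for s in self.samples if s.sequenced]
        )

    def assayed_subset(self) -> "HaplotypeMatrix":
        return self.subset(
            sites=[s.locus_id for s in self.sites if s.assayed]
        )

    # -- comparisons -------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"<HaplotypeMatrix {self.n_samples} samples x {self.n_sites} sites>"
        )

    def with_calls(self, calls: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.sites, self.samples, calls, dict(self.metadata))


def derived_sites(row: np.ndarray) -> frozenset[int]:
    """Site indices at which a call row carries the derived allele."""
    return frozenset(int(i) for i in np.flatnonzero(row == Call.DERIVED))
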