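"""Synthetic data with the statistical structure the pipeline assumes.

Three generators: (1) infinite-sites haplotypes on a two-clade genealogy
with a nested subclade, for network construction and rho calibration tests;
(2) per-site pooled depths from a labeled negative-binomial mixture shaped
like capture-sequencing coverage, for the depth classifier; (3) nucleotide
pairs/trios evolved under the T92 substitution model, for distance
estimation.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .depth import DepthProfile
from .matrix import Call, HaplotypeMatrix, SampleDef, SiteDef

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# split genealogy under infinite sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitModelParams:
    """Two clades diverging at relative depth ``t_total``; clade B carries a
    nested subclade of age ``t_clade`` (the secondary-transfer history: the
    basal intercontinental split, then a younger common ancestor of the
    transferred lineage).  ``mu`` is the expected number of mutations per
    lineage per unit depth; each mutation hits a fresh site (infinite
    sites), drawn from a pool of ``L`` sites."""

    n_per_pop: int = 8
    L: int = 2000
    t_total: float = 1.0
    t_clade: float = 0.25
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_clade < self.t_total):
            raise ValueError("need 0 < t_clade < t_total")
        if self.n_per_pop < 1 or self.L < 1 or self.mu < 0:
            raise ValueError("invalid split-model parameters")


@dataclass
class SplitTruth:
    clade_members: list[str]
    other_members: list[str]
    clade_ancestor: np.ndarray  # true state vector of the nested clade MRCA
    t_total: float
    t_clade: float
    expected_total_depth: float  # mu * t_total
    expected_clade_depth: float  # mu * t_clade


def simulate_split_haplotypes(
    p: SplitModelParams,
) -> tuple[HaplotypeMatrix, SplitTruth]:
    """Drop Poisson(mu x branch length) mutations on a rooted genealogy.

    Clade A individuals hang directly off the root with branch length
    ``t_total``; clade B individuals hang off a nested ancestor at depth
    ``t_total - t_clade`` below the root, with terminal branches of length
    ``t_clade``.  Every individual is therefore ``t_total`` deep (clock),
    and the nested clade's expected rho is ``mu * t_clade``.  Only sites hit
    by a mutation appear in the returned matrix; a site is never hit twice,
    so the data are homoplasy-free.  Raises when the site pool ``L`` is
    exhausted.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_per_pop
    expected = p.mu * ((p.t_total - p.t_clade) + n * (p.t_total + p.t_clade))
    if expected > 0.1 * p.L:
        import warnings

        warnings.warn(
            f"expected {expected:.0f} mutations against a pool of L={p.L} "
            "sites; the infinite-sites approximation may be strained",
            stacklevel=2,
        )
    a_ids = [f"A{i:03d}" for i in range(1, n + 1)]
    b_ids = [f"B{i:03d}" for i in range(1, n + 1)]

    # branches: (carriers, length)
    branches: list[tuple[list[str], float]] = []
    branches.append((b_ids, p.t_total - p.t_clade))  # stem of nested clade
    for s in a_ids:
        branches.append(([s], p.t_total))
    for s in b_ids:
        branches.append(([s], p.t_clade))

    n_mut = rng.poisson([p.mu * length for _, length in branches])
    total = int(n_mut.sum())
    if total > p.L:
        raise ValueError(
            f"site pool exhausted: {total} mutations drawn but L={p.L}; "
            "increase L"
        )

    all_ids = a_ids + b_ids
    row_of = {s: i for i, s in enumerate(all_ids)}
    calls = np.zeros((len(all_ids), total), dtype=np.int8)
    stem_sites: list[int] = []
    site = 0
    for (carriers, _length), k in zip(branches, n_mut):
        for _ in range(k):
            for s in carriers:
                calls[row_of[s], site] = Call.DERIVED
            if carriers is b_ids:
                stem_sites.append(site)
            site += 1

    sites = [
        SiteDef(locus_id=f"s{j:04d}", ancestral_allele="A", derived_allele="G")
        for j in range(total)
    ]
    samples = [
        SampleDef(identifier=s, population="cladeA" if s in a_ids else "cladeB")
        for s in all_ids
    ]
    m = HaplotypeMatrix(sites, samples, calls)
    clade_anc = np.zeros(total, dtype=np.uint8)
    clade_anc[stem_sites] = 1
    truth = SplitTruth(
        clade_members=b_ids, other_members=a_ids, clade_ancestor=clade_anc,
        t_total=p.t_total, t_clade=p.t_clade,
        expected_total_depth=p.mu * p.t_total,
        expected_clade_depth=p.mu * p.t_clade,
    )
    return m, truth


# ---------------------------------------------------------------------------
# depth mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthMixtureParams:
    """Four-component pooled-depth mixture: error, unique-Y, two-paralog and
    multi-paralog (repeat) sites.

    Component means mirror a capture experiment pooling ~19 males: spurious
    alignments near zero, a unique-Y mode near 85x, a doubled mode near
    185x where an X gametolog co-captures, and an overdispersed repeat tail.
    ``dispersions`` are negative-binomial size parameters (smaller = more
    overdispersed); ``het_probs`` give the chance that a site of each class
    shows a heterozygous call in some male.
    """

    means: tuple[float, ...] = (3.0, 85.0, 185.0, 400.0)
    dispersions: tuple[float, ...] = (2.0, 40.0, 60.0, 2.0)
    proportions: tuple[float, ...] = (0.05, 0.853, 0.05, 0.047)
    het_probs: tuple[float, ...] = (0.0, 0.0, 0.6, 0.6)
    n_sites: int = 5000
    n_samples: int = 19
    seed: int = 0
    family: str = "nb"  # "nb" | "poisson"

    def __post_init__(self) -> None:
        k = len(self.means)
        if not (len(self.dispersions) == len(self.proportions)
                == len(self.het_probs) == k):
            raise ValueError("component parameter tuples differ in length")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.family not in ("nb", "poisson"):
            raise ValueError(f"unknown depth family {self.family!r}")


#: truth labels for the four mixture components, index-aligned with params
DEPTH_CLASS_NAMES = ("ERROR", "UNIQUE_Y", "TWO_PARALOG", "MULTI_PARALOG")


def simulate_depth_profiles(
    p: DepthMixtureParams,
) -> tuple[list[DepthProfile], list[str]]:
    """Draw labeled per-site pooled depths from the mixture.

    Pooled depth is split across ``n_samples`` males multinomially so the
    per-sample depths are consistent with the pooled total.  Returns the
    profiles and the generating class label of each site.
    """
    rng = np.random.default_rng(p.seed)
    comp = rng.choice(len(p.means), size=p.n_sites, p=p.proportions)
    depths = np.empty(p.n_sites, dtype=np.int64)
    for k, (mean, size) in enumerate(zip(p.means, p.dispersions)):
        mask = comp == k
        n_k = int(mask.sum())
        if n_k == 0:
            continue
        if p.family == "poisson":
            depths[mask] = rng.poisson(mean, size=n_k)
        else:
            prob = size / (size + mean)
            depths[mask] = rng.negative_binomial(size, prob, size=n_k)
    het = rng.random(p.n_sites) < np.asarray(p.het_probs)[comp]
    profiles = []
    for j in range(p.n_sites):
        per = rng.multinomial(depths[j], np.full(p.n_samples, 1 / p.n_samples))
        profiles.append(
            DepthProfile(site_index=j, pooled_depth=int(depths[j]),
                         per_sample_depth=tuple(int(x) for x in per),
                         het_flag=bool(het[j]))
        )
    labels = [DEPTH_CLASS_NAMES[k] for k in comp]
    return profiles, labels


# ---------------------------------------------------------------------------
# T92 sequence evolution
# ---------------------------------------------------------------------------

def _t92_rate_matrix(theta: float, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """T92 generator (order ACGT) normalised to one expected substitution
    per site per unit branch length, with its stationary distribution."""
    if not (0 < theta < 1):
        raise ValueError("theta must be in (0, 1)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    pi = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float((pi * np.diag(q)).sum())
    return q / rate, pi


def _evolve(seq_idx: np.ndarray, q: np.ndarray, d: float,
            rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return seq_idx.copy()
    p = expm(q * d)
    p = np.clip(p, 0, None)
    p /= p.sum(axis=1, keepdims=True)
    out = np.empty_like(seq_idx)
    u = rng.random(seq_idx.size)
    cum = np.cumsum(p, axis=1)
    for b in range(4):
        mask = seq_idx == b
        out[mask] = np.searchsorted(cum[b], u[mask], side="right")
    return np.clip(out, 0, 3)


def simulate_t92_alignment(
    length: int,
    d_true: float,
    theta: float = 0.5,
    kappa_equivalent: float = 2.0,
    seed: int | None = None,
) -> tuple[str, str]:
    """Evolve a pair of sequences separated by total distance ``d_true``.

    The ancestor is drawn from the T92 stationary distribution (GC content
    ``theta``) and one copy evolves along a branch of ``d_true`` expected
    substitutions per site.
    """
    if d_true < 0 or length < 1:
        raise ValueError("invalid length or distance")
    rng = np.random.default_rng(seed)
    q, pi = _t92_rate_matrix(theta, kappa_equivalent)
    anc = rng.choice(4, size=length, p=pi)
    der = _evolve(anc, q, d_true, rng)
    return "".join(_BASES[anc]), "".join(_BASES[der])


def simulate_clock_trio(
    length: int,
    d_ingroup: float,
    d_outgroup: float,
    theta: float = 0.5,
    kappa_equivalent: float = 2.0,
    seed: int | None = None,
) -> dict[str, str]:
    """Three sequences on a clock tree: ingroup pair A, B with pairwise
    distance ``d_ingroup``; outgroup O at pairwise distance ``d_outgroup``
    from each."""
    if not (0 <= d_ingroup <= d_outgroup):
        raise ValueError("need 0 <= d_ingroup <= d_outgroup")
    rng = np.random.default_rng(seed)
    q, pi = _t92_rate_matrix(theta, kappa_equivalent)
    root = rng.choice(4, size=length, p=pi)
    o = _evolve(root, q, d_outgroup / 2, rng)
    mrca = _evolve(root, q, (d_outgroup - d_ingroup) / 2, rng)
    a = _evolve(mrca, q, d_ingroup / 2, rng)
    b = _evolve(mrca, q, d_ingroup / 2, rng)
    return {
        "A": "".join(_BASES[a]),
        "B": "".join(_BASES[b]),
        "O": "".join(_BASES[o]),
    }
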