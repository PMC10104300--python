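"""Per-site conservation (base-20 entropy) and between-group KL divergence.

Conservation at one alignment column is the Shannon entropy of its
amino-acid frequency distribution, taken with a base-20 logarithm so that

    S = -sum_j p_j log20 p_j

spans [0, 1]: 0 for a fully conserved site (one residue type) and 1 for a
site uniform over the 20 standard amino acids.  Gaps and ambiguity letters
are missing data: they enter neither the frequencies nor the entropy, but
they do lower the site's non-gap fraction, which is used as a coverage
filter when reporting conserved sites.

Divergence between two subfamilies at one site is the Kullback-Leibler
divergence between their per-site distributions,

    D_KL(p || q) = sum_j p_j ln(p_j / q_j)

with the natural logarithm, computed in both directions because KL is
asymmetric.  Counts are smoothed with an additive pseudocount before the
ratio is formed, since an unsmoothed KL is infinite wherever q lacks
support that p has.  Sites that are conserved within one group but occupied
by a different residue in the other rank highest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from famcons.sequence_io import AMINO_ACIDS, GAP, ProjectedAlignment

LOG20 = math.log(20.0)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class SiteDistribution:
    """Amino-acid counts and frequencies of one alignment column.

    ``counts`` holds raw counts of the 20 standard residues (ambiguity
    letters and gaps excluded); ``freqs`` the normalized probabilities;
    ``nongap_fraction`` is ``n_observed`` over the number of rows analysed.
    """

    site_number: int
    counts: np.ndarray
    n_rows: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20,):
            raise ValueError("counts must be a length-20 vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_observed(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        n = self.counts.sum()
        if n == 0:
            return np.zeros(20)
        return self.counts / n

    @property
    def nongap_fraction(self) -> float:
        return self.n_observed / self.n_rows if self.n_rows else 0.0

    def smoothed(self, pseudocount: float) -> np.ndarray:
        """Frequencies after adding ``pseudocount`` to each of the 20 counts."""
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        c = self.counts + pseudocount
        total = c.sum()
        if total == 0:
            raise ValueError(f"site {self.site_number}: no observations and zero pseudocount")
        return c / total

    def consensus(self) -> str | None:
        """Most frequent standard residue; ties broken alphabetically; None if empty."""
        if self.n_observed == 0:
            return None
        best = np.flatnonzero(self.counts == self.counts.max())[0]
        return AMINO_ACIDS[best]


@dataclass
class ConservationProfile:
    """Per-reference-site entropy, coverage and consensus for one row subset."""

    site_numbers: list[int]
    entropy: np.ndarray          # NaN where the site has no observed residues
    nongap_fraction: np.ndarray
    consensus: list[str | None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.site_numbers,
                "entropy": self.entropy,
                "frac": self.nongap_fraction,
                "amino_acid": [c if c is not None else "-" for c in self.consensus],
            }
        )

    def entropy_at(self, site_number: int) -> float:
        return float(self.entropy[self.site_numbers.index(site_number)])

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.entropy)


@dataclass
class DivergenceProfile:
    """Bidirectional per-site KL between two groups plus within-group entropies.

    ``kl_1`` uses group 1 as the reference distribution p, ``kl_2`` group 2.
    ``modal_1``/``modal_2`` are the most common characters per group counted
    over all characters including gaps, so a gap-majority site shows '-',
    as insertion/deletion differences between subfamilies are informative.
    """

    site_numbers: list[int]
    kl_1: np.ndarray
    kl_2: np.ndarray
    s_1: np.ndarray
    s_2: np.ndarray
    modal_1: list[str]
    modal_2: list[str]
    group_labels: tuple[str, str] = ("group1", "group2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "res_num": self.site_numbers,
                "KL_1": self.kl_1,
                "KL_2": self.kl_2,
                "S_1": self.s_1,
                "S_2": self.s_2,
                self.group_labels[0]: self.modal_1,
                self.group_labels[1]: self.modal_2,
            }
        )

    def ranked_table(self, s_conserved: float = 0.2) -> pd.DataFrame:
        """Sites sorted by max(KL_1, KL_2) descending, flagging those conserved
        in at least one group (S below ``s_conserved``) yet divergent."""
        df = self.to_frame()
        df["max_kl"] = np.fmax(df["KL_1"], df["KL_2"])
        df["conserved_in_one"] = (df["S_1"] < s_conserved) | (df["S_2"] < s_conserved)
        df = df.sort_values(["max_kl", "res_num"], ascending=[False, True], kind="mergesort")
        return df.reset_index(drop=True)


def column_frequencies(
    projection: ProjectedAlignment,
    site_number: int,
    rows: Sequence[int] | None = None,
) -> SiteDistribution:
    """Count the 20 standard residues in one projected column.

    Gaps and ambiguity letters (B, Z, X, U, O) are excluded from the counts
    — they are missing data — but every analysed row contributes to the
    non-gap fraction's denominator.
    """
    if rows is not None and len(rows) == 0:
        raise ValueError("row subset is empty")
    col = projection.column(site_number, rows)
    counts = np.zeros(20)
    for ch in col:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    return SiteDistribution(site_number=site_number, counts=counts, n_rows=len(col))


def site_entropy(dist: SiteDistribution) -> float:
    """Base-20 Shannon entropy of one site; NaN when nothing is observed.

    Terms with p_j = 0 contribute 0.  S = 0 iff a single residue type is
    observed; S = 1 iff all 20 types are equally frequent.
    """
    if dist.n_observed == 0:
        return float("nan")
    p = dist.freqs
    nz = p > 0
    s = float(-(p[nz] * np.log(p[nz])).sum() / LOG20)
    return s if s > 0.0 else 0.0  # avoid -0.0 from rounding


def entropy_profile(
    projection: ProjectedAlignment,
    rows: Sequence[int] | None = None,
) -> ConservationProfile:
    """Entropy, non-gap fraction and consensus for every projected site."""
    entropies, fracs, consensus = [], [], []
    for site in projection.site_numbers:
        dist = column_frequencies(projection, site, rows)
        entropies.append(site_entropy(dist))
        fracs.append(dist.nongap_fraction)
        consensus.append(dist.consensus())
    return ConservationProfile(
        site_numbers=list(projection.site_numbers),
        entropy=np.array(entropies),
        nongap_fraction=np.array(fracs),
        consensus=consensus,
    )


def conserved_sites(
    profile: ConservationProfile,
    s_max: float = 0.1,
    frac_min: float = 0.7,
) -> pd.DataFrame:
    """Sites with S <= s_max and non-gap fraction > frac_min, by site number.

    The default thresholds select highly conserved (S <= 0.1), well-covered
    (> 70% non-gap) positions; S < 0.2 is the looser "conserved" cut used
    for very diverse sequence sets.
    """
    for name, t in (("s_max", s_max), ("frac_min", frac_min)):
        if not (0 < t <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    df = profile.to_frame()
    mask = profile.defined & (profile.entropy <= s_max) & (profile.nongap_fraction > frac_min)
    return df[mask].reset_index(drop=True)


def kl_divergence(p: SiteDistribution, q: SiteDistribution, pseudocount: float = 0.5) -> float:
    """Kullback-Leibler divergence sum_j p_j ln(p_j/q_j) on smoothed counts.

    Both distributions get ``pseudocount`` added to each of the 20 counts
    and are renormalized; with pseudocount 0 the value is finite only where
    q covers p's support (0 ln 0 terms are 0).  NaN if either site has no
    observations.
    """
    if p.n_observed == 0 or q.n_observed == 0:
        return float("nan")
    if pseudocount > 0:
        pf, qf = p.smoothed(pseudocount), q.smoothed(pseudocount)
    else:
        pf, qf = p.freqs, q.freqs
    nz = pf > 0
    with np.errstate(divide="ignore"):
        ratio = np.log(pf[nz] / qf[nz])
    return float((pf[nz] * ratio).sum())


def _modal_with_gaps(column: np.ndarray) -> str:
    """Most common character including gaps; ambiguity letters ignored;
    ties prefer a residue over '-' then alphabetical order."""
    chars, counts = np.unique(column, return_counts=True)
    keep = [i for i, c in enumerate(chars) if c in _AA_INDEX or c == GAP]
    if not keep:
        return GAP
    chars, counts = chars[keep], counts[keep]
    order = sorted(range(len(chars)), key=lambda i: (-counts[i], chars[i] == GAP, chars[i]))
    return str(chars[order[0]])


def divergence_profile(
    projection: ProjectedAlignment,
    group1_rows: Sequence[int],
    group2_rows: Sequence[int],
    pseudocount: float = 0.5,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> DivergenceProfile:
    """Per-site bidirectional KL and within-group entropies for two groups."""
    g1, g2 = list(group1_rows), list(group2_rows)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")

    kl1, kl2, s1, s2, m1, m2 = [], [], [], [], [], []
    for site in projection.site_numbers:
        d1 = column_frequencies(projection, site, g1)
        d2 = column_frequencies(projection, site, g2)
        kl1.append(kl_divergence(d1, d2, pseudocount))
        kl2.append(kl_divergence(d2, d1, pseudocount))
        s1.append(site_entropy(d1))
        s2.append(site_entropy(d2))
        m1.append(_modal_with_gaps(projection.column(site, g1)))
        m2.append(_modal_with_gaps(projection.column(site, g2)))
    return DivergenceProfile(
        site_numbers=list(projection.site_numbers),
        kl_1=np.array(kl1),
        kl_2=np.array(kl2),
        s_1=np.array(s1),
        s_2=np.array(s2),
        modal_1=m1,
        modal_2=m2,
        group_labels=group_labels,
    )
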