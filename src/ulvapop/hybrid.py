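"""F1 hybrid detection from 45S allelic frequencies and organellar homoplasmy.

The multi-copy nuclear 45S rDNA behaves as a pooled allele population: in an
F1 hybrid roughly half the repeat copies carry each parent's alleles, so read
frequencies at sites fixed for different alleles in the two parent species
("informative sites") sit near 0.5 at every site.  Organelles, by contrast,
are uniparentally inherited, so a true F1 is homoplasmic for a single
parent's chloroplast and mitochondrion.  A strain is called F1 only when both
signatures hold; a pure nuclear call that disagrees with the organellar
assignment is flagged discordant (possible introgression / later-generation
hybrid) rather than F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import seq as sq
from .mapvar import Pileup

NUC_A = "A"
NUC_B = "B"
NUC_HET = "heterozygous_AB"
NUC_AMBIGUOUS = "ambiguous"

VERDICT_PURE = "pure"
VERDICT_F1 = "F1_hybrid"
VERDICT_DISCORDANT = "discordant_non_F1"
VERDICT_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class InformativeSite:
    """A position fixed for different alleles in species A and B."""

    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValueError("informative site alleles must differ")


@dataclass
class AlleleFrequencyProfile:
    """Per-strain allele-A frequencies at the informative sites."""

    strain_id: str
    sites: list[InformativeSite]
    depth: np.ndarray        # A+B reads per site (0 where below min depth)
    freq_a: np.ndarray       # NaN where depth insufficient
    noise: np.ndarray        # fraction of reads that are neither allele

    @property
    def usable(self) -> np.ndarray:
        return ~np.isnan(self.freq_a)

    @property
    def mean_freq(self) -> float:
        return float(np.nanmean(self.freq_a)) if self.usable.any() else float("nan")

    def het_fraction(self, band: tuple[float, float] = (0.35, 0.65)) -> float:
        f = self.freq_a[self.usable]
        if f.size == 0:
            return float("nan")
        return float(np.mean((f >= band[0]) & (f <= band[1])))


@dataclass
class HybridReport:
    strain_id: str
    nuclear_call: str
    cp_call: str
    mt_call: str
    cp_homoplasmic: bool
    mt_homoplasmic: bool
    verdict: str
    detail: dict = field(default_factory=dict)


def find_informative_sites(
    consensus_a: str,
    consensus_b: str,
    pileups_a: Sequence[Pileup] = (),
    pileups_b: Sequence[Pileup] = (),
    fixation_threshold: float = 0.95,
    min_depth: int = 10,
) -> list[InformativeSite]:
    """Sites where the two species consensuses differ and, when per-species
    strain pileups are supplied, each species' pooled reads support its own
    allele at >= ``fixation_threshold``.  Sorted by position."""
    a, b = sq.encode(consensus_a), sq.encode(consensus_b)
    if a.size != b.size:
        raise ValueError("consensuses must be on common coordinates")
    diff = np.nonzero(a != b)[0]
    pooled_a = _pooled_counts(pileups_a, a.size)
    pooled_b = _pooled_counts(pileups_b, a.size)
    sites = []
    for p in diff:
        ok = True
        for pooled, allele in ((pooled_a, a[p]), (pooled_b, b[p])):
            if pooled is None:
                continue
            depth = pooled[:, p].sum()
            if depth < min_depth or pooled[allele, p] / depth < fixation_threshold:
                ok = False
                break
        if ok:
            sites.append(InformativeSite(int(p), sq.BASES[a[p]], sq.BASES[b[p]]))
    if not sites:
        warnings.warn("no informative sites between consensuses")
    return sites


def _pooled_counts(pileups: Sequence[Pileup], length: int) -> np.ndarray | None:
    if not pileups:
        return None
    total = np.zeros((4, length), dtype=np.int64)
    for p in pileups:
        if p.length != length:
            raise ValueError("pileup length mismatch")
        total += p.counts
    return total


def allele_profile(
    pileup: Pileup,
    sites: Sequence[InformativeSite],
    strain_id: str = "",
    min_depth: int = 10,
) -> AlleleFrequencyProfile:
    """Per-site frequency of allele A among (A + B) reads; other bases are
    tracked as noise.  Sites with A+B depth below ``min_depth`` are NaN."""
    n = len(sites)
    depth = np.zeros(n, dtype=int)
    freq = np.full(n, np.nan)
    noise = np.full(n, np.nan)
    for i, s in enumerate(sites):
        col = pileup.counts[:, s.position]
        ca = int(col[sq.BASES.index(s.allele_a)])
        cb = int(col[sq.BASES.index(s.allele_b)])
        tot = int(col.sum())
        depth[i] = ca + cb
        if ca + cb >= min_depth:
            freq[i] = ca / (ca + cb)
            noise[i] = (tot - ca - cb) / tot if tot else np.nan
    if not np.any(~np.isnan(freq)):
        warnings.warn(f"strain {strain_id}: all informative sites below depth")
    return AlleleFrequencyProfile(strain_id, list(sites), depth, freq, noise)


def classify_nuclear(
    profile: AlleleFrequencyProfile,
    het_band: tuple[float, float] = (0.35, 0.65),
    site_majority: float = 0.9,
    alpha: float = 0.01,
    min_informative_sites: int = 5,
    max_flipped_fraction: float = 0.2,
) -> tuple[str, dict]:
    """Classify the 45S pool as parent A, parent B, heterozygous A/B, or
    ambiguous.

    heterozygous_AB requires the pooled allele ratio (depth-weighted mean of
    in-band frequencies, ~0.5 up to the binomial copy-number split of the two
    parental rDNA arrays) to lie inside the heterozygous band, >=
    ``site_majority`` of usable sites to be het-consistent, and no in-band
    site to reject the pooled ratio in an exact binomial test at the
    Bonferroni-corrected ``alpha``.  A site is het-consistent when it lies in
    the band or when the binomial test cannot distinguish it from the pooled
    ratio -- a hard band edge alone would misclassify sites that are pure
    sampling fluctuations around a legitimately off-centre copy ratio.  The
    pooled ratio is the quantity every informative site of a genuine F1 must
    share, so sites with genuinely different intermediate ratios (chimeric or
    partial patterns) still veto the call, while fully flipped sites (a
    strain-private rDNA variant recoding one informative locus) are simply
    excluded from the majority.  A (resp. B) requires >= ``site_majority`` of
    frequencies above 0.9 (resp. below 0.1).
    """
    use = profile.usable
    n = int(use.sum())
    detail: dict = {"n_sites_used": n}
    if n < min_informative_sites:
        detail["reason"] = f"only {n} informative sites with depth"
        return NUC_AMBIGUOUS, detail
    f = profile.freq_a[use]
    d = profile.depth[use]
    frac_het = float(np.mean((f >= het_band[0]) & (f <= het_band[1])))
    frac_a = float(np.mean(f > 0.9))
    frac_b = float(np.mean(f < 0.1))
    detail.update(frac_in_het_band=frac_het, frac_a=frac_a, frac_b=frac_b, mean_freq=float(f.mean()))
    in_band = (f >= het_band[0]) & (f <= het_band[1])
    if in_band.any():
        fb, db = f[in_band], d[in_band]
        pooled = float(np.sum(fb * db) / np.sum(db))
        bonf = alpha / n
        pvals = np.array([binomtest(int(round(fi * di)), int(di), pooled).pvalue for fi, di in zip(f, d)])
        # a site pinned near 0 or 1 that firmly rejects the pooled ratio has
        # lost its diagnostic allele in this strain (private rDNA variant):
        # it is no longer informative here and leaves the denominator -- but
        # only a small fraction of sites may be explained away like this,
        # so chimeric patterns (many flipped loci) still fail the call
        flipped = (~in_band) & (pvals < bonf) & ((f < 0.1) | (f > 0.9))
        if flipped.sum() > max_flipped_fraction * n:
            flipped[:] = False
        eff = ~flipped
        consistent = in_band | (pvals >= bonf)
        frac_consistent = float(consistent[eff].mean()) if eff.any() else 0.0
        detail.update(
            pooled_ratio=pooled, min_binom_p=float(pvals.min()),
            n_recoded_sites=int(flipped.sum()), frac_het_consistent=frac_consistent,
        )
        if (
            int(eff.sum()) >= min_informative_sites
            and het_band[0] <= pooled <= het_band[1]
            and frac_consistent >= site_majority
        ):
            if np.all(pvals[in_band] >= bonf):
                return NUC_HET, detail
            detail["reason"] = "binomial test rejects the shared pooled ratio at an in-band site"
            return NUC_AMBIGUOUS, detail
    if frac_a >= site_majority:
        return NUC_A, detail
    if frac_b >= site_majority:
        return NUC_B, detail
    detail["reason"] = "no allele pattern reaches site majority"
    return NUC_AMBIGUOUS, detail


def check_homoplasmy(
    pileup: Pileup,
    consensus_a: str,
    consensus_b: str,
    max_minor: float = 0.05,
    min_depth: int = 10,
    mixture_band: tuple[float, float] = (0.2, 0.8),
    intermediate_tolerance: float = 0.02,
) -> tuple[str, bool]:
    """Organellar species call and homoplasmy flag from diagnostic sites.

    The call is the species whose alleles dominate the diagnostic sites (mean
    allele-A fraction >= 1 - max_minor, or <= max_minor for the other
    species).  Heteroplasmy -- a genuine mixture of two organellar
    haplotypes -- shows clearly intermediate frequencies (inside
    ``mixture_band``) at essentially *every* diagnostic site, whereas a
    homoplasmic strain shows frequencies pinned near 0 or 1: sequencing
    errors perturb single sites only slightly, and a private substitution
    that happens to recreate the other species' allele flips a site fully
    rather than making it intermediate.  The strain is therefore homoplasmic
    iff the fraction of diagnostic sites inside the mixture band is <=
    ``intermediate_tolerance``.  A mixed aggregate signal (neither species
    dominating) yields ("ambiguous", False).
    """
    a, b = sq.encode(consensus_a), sq.encode(consensus_b)
    diff = np.nonzero(a != b)[0]
    if diff.size == 0:
        raise ValueError("no diagnostic sites between organellar consensuses")
    fa = []
    for p in diff:
        col = pileup.counts[:, p]
        ca, cb = int(col[a[p]]), int(col[b[p]])
        if ca + cb >= min_depth:
            fa.append(ca / (ca + cb))
    if not fa:
        return VERDICT_AMBIGUOUS, False
    fa_arr = np.array(fa)
    agg = float(fa_arr.mean())
    intermediate = (fa_arr > mixture_band[0]) & (fa_arr < mixture_band[1])
    homoplasmic = bool(intermediate.mean() <= intermediate_tolerance)
    if agg >= 1 - max_minor:
        return "A", homoplasmic
    if agg <= max_minor:
        return "B", homoplasmic
    if agg >= 0.65:
        return "A", False
    if agg <= 0.35:
        return "B", False
    return VERDICT_AMBIGUOUS, False


def call_hybrid(
    strain_id: str,
    nuclear_call: str,
    cp_call: str,
    mt_call: str,
    cp_homoplasmic: bool,
    mt_homoplasmic: bool,
    detail: dict | None = None,
) -> HybridReport:
    """Combine nuclear and organellar evidence into a per-strain verdict.

    F1_hybrid  iff nuclear is heterozygous_AB and both organelles are
               homoplasmic for one and the same parent;
    pure       iff nuclear and both organellar calls agree on one species;
    discordant_non_F1 iff nuclear is a pure call differing from the
               organellar call (possible introgression, not an F1).
    """
    organelles_agree = cp_call == mt_call and cp_call in (NUC_A, NUC_B)
    both_homoplasmic = cp_homoplasmic and mt_homoplasmic
    if nuclear_call == NUC_HET and organelles_agree and both_homoplasmic:
        verdict = VERDICT_F1
    elif nuclear_call in (NUC_A, NUC_B) and organelles_agree and nuclear_call == cp_call and both_homoplasmic:
        verdict = VERDICT_PURE
    elif nuclear_call in (NUC_A, NUC_B) and organelles_agree and nuclear_call != cp_call:
        verdict = VERDICT_DISCORDANT
    else:
        verdict = VERDICT_AMBIGUOUS
    return HybridReport(
        strain_id, nuclear_call, cp_call, mt_call, cp_homoplasmic, mt_homoplasmic, verdict, detail or {}
    )


def call_hybrids(inputs: Sequence[Mapping]) -> tuple[list[HybridReport], pd.DataFrame]:
    """Panel-level verdicts plus a summary count per verdict class."""
    reports = [
        call_hybrid(
            d["strain_id"], d["nuclear_call"], d["cp_call"], d["mt_call"],
            d["cp_homoplasmic"], d["mt_homoplasmic"], d.get("detail"),
        )
        for d in inputs
    ]
    counts = pd.Series([r.verdict for r in reports]).value_counts()
    summary = pd.DataFrame({"verdict": counts.index, "n_strains": counts.values})
    return reports, summary
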