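"""Nucleotide diversity per site, per functional class and per window.

The per-site estimator is the unbiased mean pairwise difference among the
n sampled haplotypes, pi = 2*(k/n)*(1-k/n)*n/(n-1) for a biallelic site
with k copies of one allele.  Class- and window-level theta_pi divide the
summed per-SNP pi by the number of *callable* sites of the class/window,
so monomorphic callable sites contribute zero to the numerator and one to
the denominator.

Windows (default 100 kb, non-overlapping, tiled from scaffold start) are
retained for a population when they contain at least ``min_coding`` coding
positions and at least a ``min_coverage`` fraction of callable sites.
Retained windows are standardized per population,

    theta_pi_Z = (window theta_pi - mean theta_pi) / SD(theta_pi),

with the sample SD (n-1) over that population's retained windows; windows
with theta_pi_Z > 0 are classified as high-diversity regions, all others
(including exact zeros) as low-diversity regions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation_sites import (
    CODING_CLASSES,
    INTERGENIC,
    INTRON,
    POS1,
    POS2,
    POS3,
    SiteClassMap,
    WindowGrid,
)
from .variant_filters import PopulationVariants

logger = logging.getLogger("leptidiv")

CLASS_SELECTORS = {
    "codon_pos1": POS1,
    "codon_pos2": POS2,
    "codon_pos3": POS3,
    "intron": INTRON,
    "intergenic": INTERGENIC,
}


def site_pi(k, n):
    """Mean pairwise difference at one biallelic site: 2k(n-k) / (n(n-1)).

    Vectorized over arrays of allele counts ``k`` and haplotype totals
    ``n``; symmetric in k and n-k, so polarization does not matter.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("site_pi requires at least 2 haplotypes")
    if np.any((k < 0) | (k > n)):
        raise ValueError("allele count k must satisfy 0 <= k <= n")
    return 2.0 * k * (n - k) / (n * (n - 1.0))


def _class_site_mask(scmap: SiteClassMap, scaffold: str, selector: str) -> np.ndarray:
    if selector == "fourfold":
        return scmap.fourfold[scaffold]
    if selector == "all":
        return ~scmap.n_mask[scaffold]
    if selector == "coding":
        return np.isin(scmap.classes[scaffold], CODING_CLASSES)
    return scmap.classes[scaffold] == CLASS_SELECTORS[selector]


def gc_conservative_subset(pv: PopulationVariants) -> PopulationVariants:
    """Retain only GC-conservative SNPs: {ref, alt} = {A, T} or {G, C}.

    Weak-to-weak and strong-to-strong changes leave GC content unchanged,
    removing the confounding of diversity contrasts by base composition.
    Callability masks are shared with the input, so class denominators are
    identical and the subset diversity is bounded by the full diversity.
    """
    out = {}
    for pop, df in pv.snps.items():
        pair = df["ref"].astype(str) + df["alt"].astype(str)
        keep = pair.isin(["AT", "TA", "GC", "CG"]).to_numpy()
        sub = df[keep].reset_index(drop=True)
        sub.attrs["fixed_alt"] = df.attrs.get("fixed_alt")
        out[pop] = sub
    return PopulationVariants(snps=out, callable_mask=pv.callable_mask, qc=dict(pv.qc))


def theta_pi_by_class(
    pv: PopulationVariants,
    scmap: SiteClassMap,
    selector: str,
    population: str,
) -> float:
    """Per-site theta_pi over callable sites of one class for one population.

    Returns 0.0 when the class has callable sites but no SNPs, and NaN when
    the class has no callable sites at all.
    """
    df = pv.snps[population]
    num = 0.0
    den = 0
    for scaf in scmap.scaffold_names:
        cmask = _class_site_mask(scmap, scaf, selector)
        call = pv.callable_mask[population][scaf]
        sel = cmask & call
        den += int(sel.sum())
        sub = df[df["scaffold"] == scaf]
        if len(sub):
            pos = sub["pos"].to_numpy()
            in_class = sel[pos]
            if in_class.any():
                num += float(
                    site_pi(
                        sub["alt_count"].to_numpy()[in_class],
                        sub["n_hap"].to_numpy()[in_class],
                    ).sum()
                )
    if den == 0:
        return float("nan")
    return num / den


def class_diversity_summary(
    pv: PopulationVariants, scmap: SiteClassMap
) -> pd.DataFrame:
    """theta_pi per population x site class, with the GC-conservative variant."""
    gc_pv = gc_conservative_subset(pv)
    selectors = ["codon_pos1", "codon_pos2", "codon_pos3", "fourfold", "intron", "intergenic"]
    rows = []
    for pop in pv.populations():
        for sel in selectors:
            rows.append(
                {
                    "population": pop,
                    "site_class": sel,
                    "theta_pi": theta_pi_by_class(pv, scmap, sel, pop),
                    "theta_pi_gc_conservative": theta_pi_by_class(
                        gc_pv, scmap, sel, pop
                    ),
                    "n_callable_sites": sum(
                        int(
                            (
                                _class_site_mask(scmap, s, sel)
                                & pv.callable_mask[pop][s]
                            ).sum()
                        )
                        for s in scmap.scaffold_names
                    ),
                }
            )
    return pd.DataFrame(rows)


def window_diversity(
    pv: PopulationVariants,
    scmap: SiteClassMap,
    grid: WindowGrid,
    min_coding: int = 1000,
    min_coverage: float = 0.5,
    exclude_terminal_short: bool = True,
) -> pd.DataFrame:
    """Per-window, per-population theta_pi and pi_4D with inclusion flags.

    A window is retained ("included") for a population when it contains at
    least ``min_coding`` coding positions and its callable fraction is at
    least ``min_coverage`` (both bounds inclusive).  Terminal short windows
    are computed but excluded by default.
    """
    if not grid.scaffold_lengths:
        raise ValueError("window grid has no scaffolds")
    frames = []
    for pop in pv.populations():
        df = pv.snps[pop]
        for scaf, length in grid.scaffold_lengths.items():
            n_win = grid.n_windows(scaf)
            widx_all = np.arange(length) // grid.window_size
            call = pv.callable_mask[pop][scaf]
            coding = np.isin(scmap.classes[scaf], CODING_CLASSES)
            ff = scmap.fourfold[scaf]

            callable_n = np.bincount(widx_all[call], minlength=n_win)
            coding_n = np.bincount(widx_all[coding], minlength=n_win)
            ff_call_n = np.bincount(widx_all[ff & call], minlength=n_win)

            pi_sum = np.zeros(n_win)
            pi4_sum = np.zeros(n_win)
            sub = df[df["scaffold"] == scaf]
            if len(sub):
                pos = sub["pos"].to_numpy()
                pis = site_pi(sub["alt_count"].to_numpy(), sub["n_hap"].to_numpy())
                wi = pos // grid.window_size
                np.add.at(pi_sum, wi, pis)
                at4 = ff[pos]
                np.add.at(pi4_sum, wi[at4], pis[at4])

            wins = grid.windows(scaf)
            sizes = np.array([e - s for s, e in wins], dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = np.where(callable_n > 0, pi_sum / np.maximum(callable_n, 1), np.nan)
                pi4 = np.where(ff_call_n > 0, pi4_sum / np.maximum(ff_call_n, 1), np.nan)
                coverage = callable_n / sizes
            terminal = sizes < grid.window_size
            included = (coding_n >= min_coding) & (coverage >= min_coverage)
            if exclude_terminal_short:
                included &= ~terminal
            frames.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "scaffold": scaf,
                        "start": [w[0] for w in wins],
                        "end": [w[1] for w in wins],
                        "theta_pi": theta,
                        "pi_4d": pi4,
                        "n_coding_sites": coding_n,
                        "n_callable_sites": callable_n,
                        "n_4d_callable": ff_call_n,
                        "coverage_fraction": coverage,
                        "is_terminal_short": terminal,
                        "included": included,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def zscore_classify(windows: pd.DataFrame, ties_to: str = "low") -> pd.DataFrame:
    """Standardize included-window theta_pi per population and classify.

    Adds ``theta_pi_z`` (mean 0, sample SD 1 over each population's
    included windows) and ``diversity_class`` ('high' iff z > 0; exact
    zeros go to ``ties_to``, 'low' by default).  Excluded windows keep
    missing z and class.  A population whose included-window theta_pi has
    zero SD aborts with a diagnostic.
    """
    out = windows.copy()
    out["theta_pi_z"] = np.nan
    out["diversity_class"] = pd.array([pd.NA] * len(out), dtype="string")
    for pop, sub in out.groupby("population", sort=False):
        inc = sub.index[sub["included"] & sub["theta_pi"].notna()]
        if len(inc) < 2:
            raise ValueError(
                f"population {pop}: need at least 2 included windows to standardize"
            )
        vals = out.loc[inc, "theta_pi"].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"population {pop}: zero SD of window theta_pi; z-scores undefined"
            )
        z = (vals - vals.mean()) / sd
        out.loc[inc, "theta_pi_z"] = z
        if ties_to == "low":
            cls = np.where(z > 0, "high", "low")
        else:
            cls = np.where(z < 0, "low", "high")
        out.loc[inc, "diversity_class"] = cls
    return out
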