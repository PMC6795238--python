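"""Synonymous/nonsynonymous site counting, pN/pS, dN/dS and MK-based alpha.

Site totals follow Nei & Gojobori (1986): each codon position contributes
(number of synonymous single-nucleotide changes)/3 to the synonymous site
total and the remainder to the nonsynonymous total, with mutations to stop
codons counted nonsynonymous, so LN + LS = 3 per sense codon exactly.

Fixed differences against an aligned outgroup are called per population: a
site is a substitution iff all callable haplotypes carry one allele and
that allele differs from the outgroup base; polymorphic sites are never
substitutions.  No multiple-hit (Jukes-Cantor) correction is applied by
default -- divergence here is shallow; a JC69 toggle is available on the
window ratios for sensitivity analysis.

The adaptive fraction alpha is the McDonald-Kreitman form
``alpha = 1 - (dS * pN) / (dN * pS)`` computed on the site-class scheme of
the windowed analysis (four-fold degenerate sites as the neutral class,
second codon positions as the selected class), with a percentile bootstrap
over genes and an optional derived-allele-frequency floor to mitigate
segregating deleterious variants.  This is deliberately the plain MK
estimator, not a DFE-based likelihood fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_sites import (
    CODON_AA,
    NG86_NONSYN_SITES,
    NG86_SYN_SITES,
    POS2,
    SiteClassMap,
    WindowGrid,
)
from .variant_filters import PopulationVariants

logger = logging.getLogger("leptidiv")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MKTable:
    """Polymorphism/substitution counts and site totals for one scope."""

    scope: str
    pn: float
    ps: float
    dn: float
    ds: float
    ln: float
    ls: float


def count_sites_ng86(codon: str, table_id: int = 1) -> tuple[float, float]:
    """NG86 fractional (nonsynonymous, synonymous) site counts for a codon.

    Raises on stop codons (excluded upstream) and on ambiguous bases.
    """
    codes = [
        _BASE_CODE.get(b)
        for b in codon.upper()
    ]
    if len(codes) != 3 or any(c is None for c in codes):
        raise ValueError(f"invalid codon {codon!r}")
    idx = codes[0] * 16 + codes[1] * 4 + codes[2]
    if table_id != 1:
        from .annotation_sites import _codon_tables

        aa, _, syn = _codon_tables(table_id)
        if aa[idx] == "*":
            raise ValueError(f"stop codon {codon!r} has no site counts")
        return float(3.0 - syn[idx]), float(syn[idx])
    if CODON_AA[idx] == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    return float(NG86_NONSYN_SITES[idx]), float(NG86_SYN_SITES[idx])


def _mutate_codon_idx(idx: int, offset: int, new_base: int) -> int:
    shift = 4 ** (2 - offset)
    cur = idx // shift % 4
    return idx + (new_base - cur) * shift


def classify_change(codon_idx: int, offset: int, alt_code: int) -> str:
    """Classify a single-base codon change: synonymous / nonsynonymous / stop_involving."""
    new_idx = _mutate_codon_idx(int(codon_idx), int(offset), int(alt_code))
    aa_old, aa_new = CODON_AA[codon_idx], CODON_AA[new_idx]
    if aa_old == "*" or aa_new == "*":
        return "stop_involving"
    return "synonymous" if aa_old == aa_new else "nonsynonymous"


def classify_polymorphisms(
    pv: PopulationVariants, scmap: SiteClassMap
) -> PopulationVariants:
    """Attach a coding classification column to every population's SNP table.

    Coding SNPs (sites inside a valid codon) become synonymous /
    nonsynonymous / stop_involving, each variant judged against the
    reference codon with the other two positions held at reference; codons
    holding two or more segregating sites additionally get a multi-hit
    flag.  SNPs whose codon context contains N (invalid codon) are
    excluded and QC-counted; non-coding SNPs get an empty classification.
    """
    scaf_idx = {s: i for i, s in enumerate(scmap.scaffold_names)}
    qc_excluded = {}
    for pop, df in pv.snps.items():
        cls_col = np.full(len(df), "", dtype=object)
        multi = np.zeros(len(df), dtype=bool)
        excluded_n = 0
        if len(df):
            cid = np.array(
                [scmap.codon_id[s][p] for s, p in zip(df["scaffold"], df["pos"])]
            )
            coff = np.array(
                [scmap.codon_offset[s][p] for s, p in zip(df["scaffold"], df["pos"])]
            )
            in_codon = cid >= 0
            valid = in_codon & scmap.codon_valid[np.clip(cid, 0, None)]
            excluded_n = int((in_codon & ~valid).sum())
            seen: dict[int, list[int]] = {}
            for row in np.flatnonzero(valid):
                seen.setdefault(int(cid[row]), []).append(row)
            for codon, rows in seen.items():
                if len(rows) > 1:
                    multi[rows] = True
                strand = scmap.codon_strand[codon]
                cidx = int(scmap.codons[codon])
                for row in rows:
                    alt = _BASE_CODE.get(str(df["alt"].iloc[row]), 4)
                    if alt >= 4:
                        cls_col[row] = "excluded_n"
                        continue
                    if strand == "-":
                        alt = 3 - alt
                    cls_col[row] = classify_change(cidx, int(coff[row]), alt)
            cls_col[in_codon & ~valid] = "excluded_n"
        df["coding_class"] = cls_col
        df["multi_hit"] = multi
        qc_excluded[pop] = excluded_n
        _ = scaf_idx  # scaffolds validated through scmap lookups above
    pv.qc["snps_excluded_invalid_codon"] = qc_excluded
    return pv


def call_substitutions(
    pv: PopulationVariants,
    scmap: SiteClassMap,
    reference: dict[str, np.ndarray],
    outgroup: dict[str, np.ndarray],
) -> dict[str, pd.DataFrame]:
    """Call per-population fixed differences against the outgroup.

    For each population, every callable non-N site where the population's
    fixed allele differs from the (non-N) outgroup base is a substitution.
    The fixed allele is the reference base except at retained records fixed
    for ALT; polymorphic sites are removed.  Coding substitutions are
    classified with the outgroup allele as ancestral state and the other
    codon positions held at reference.
    """
    subs: dict[str, pd.DataFrame] = {}
    for pop, df in pv.snps.items():
        rows = []
        fixed_alt = df.attrs.get("fixed_alt")
        for scaf in scmap.scaffold_names:
            ref = reference[scaf]
            out = outgroup[scaf]
            if len(out) != len(ref):
                raise ValueError(
                    f"outgroup length mismatch on {scaf}: {len(out)} vs {len(ref)}"
                )
            call = pv.callable_mask[pop][scaf]
            cand = (out != ref) & (out < 4) & (ref < 4) & call
            # polymorphic sites are never substitutions
            poly_pos = df.loc[df["scaffold"] == scaf, "pos"].to_numpy(dtype=np.int64)
            cand[poly_pos] = False
            pop_allele = ref.astype(np.int16).copy()
            if fixed_alt is not None and len(fixed_alt):
                fa = fixed_alt[fixed_alt["scaffold"] == scaf]
                for p, a in zip(fa["pos"], fa["alt"]):
                    code = _BASE_CODE.get(str(a), 4)
                    if code < 4 and call[p] and out[p] < 4:
                        pop_allele[p] = code
                        cand[p] = out[p] != code
            positions = np.flatnonzero(cand)
            if not len(positions):
                continue
            cid = scmap.codon_id[scaf][positions]
            coff = scmap.codon_offset[scaf][positions]
            ff = scmap.fourfold[scaf][positions]
            cls = scmap.classes[scaf][positions]
            classification = np.full(len(positions), "", dtype=object)
            in_codon = cid >= 0
            valid = in_codon & scmap.codon_valid[np.clip(cid, 0, None)]
            for i in np.flatnonzero(valid):
                codon = int(cid[i])
                strand = scmap.codon_strand[codon]
                cidx = int(scmap.codons[codon])
                anc = int(out[positions[i]])
                der = int(pop_allele[positions[i]])
                if strand == "-":
                    anc, der = 3 - anc, 3 - der
                anc_idx = _mutate_codon_idx(cidx, int(coff[i]), anc)
                der_idx = _mutate_codon_idx(cidx, int(coff[i]), der)
                aa_a, aa_d = CODON_AA[anc_idx], CODON_AA[der_idx]
                if aa_a == "*" or aa_d == "*":
                    classification[i] = "stop_involving"
                elif aa_a == aa_d:
                    classification[i] = "synonymous"
                else:
                    classification[i] = "nonsynonymous"
            classification[in_codon & ~valid] = "excluded_n"
            rows.append(
                pd.DataFrame(
                    {
                        "scaffold": scaf,
                        "pos": positions,
                        "site_class": cls,
                        "fourfold": ff,
                        "codon_id": cid,
                        "classification": classification,
                    }
                )
            )
        subs[pop] = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(
                columns=[
                    "scaffold",
                    "pos",
                    "site_class",
                    "fourfold",
                    "codon_id",
                    "classification",
                ]
            )
        )
    return subs


def _codon_window_sites(
    pv: PopulationVariants, scmap: SiteClassMap, grid: WindowGrid, population: str
) -> pd.DataFrame:
    """Per-window NG86 site totals over valid codons fully callable in the population."""
    n_codons = len(scmap.codons)
    rows = []
    if n_codons:
        call_ok = np.zeros(n_codons, dtype=bool)
        mask = pv.callable_mask[population]
        for si, scaf in enumerate(scmap.scaffold_names):
            sel = scmap.codon_scaffold == si
            if not sel.any():
                continue
            sites = scmap.codon_sites[sel]
            call_ok[sel] = mask[scaf][sites].all(axis=1)
        usable = call_ok & scmap.codon_valid & (scmap.codons >= 0)
        syn = np.where(usable, NG86_SYN_SITES[np.clip(scmap.codons, 0, 63)], 0.0)
        nonsyn = np.where(usable, NG86_NONSYN_SITES[np.clip(scmap.codons, 0, 63)], 0.0)
        first_site = scmap.codon_sites[:, 0] if n_codons else np.empty(0, np.int64)
        for si, scaf in enumerate(scmap.scaffold_names):
            n_win = grid.n_windows(scaf)
            sel = scmap.codon_scaffold == si
            widx = first_site[sel] // grid.window_size
            ls = np.bincount(widx, weights=syn[sel], minlength=n_win)[:n_win]
            ln = np.bincount(widx, weights=nonsyn[sel], minlength=n_win)[:n_win]
            wins = grid.windows(scaf)
            rows.append(
                pd.DataFrame(
                    {
                        "scaffold": scaf,
                        "start": [w[0] for w in wins],
                        "end": [w[1] for w in wins],
                        "ln": ln,
                        "ls": ls,
                    }
                )
            )
    if not rows:
        tab = grid.table()[["scaffold", "start", "end"]].copy()
        tab["ln"] = 0.0
        tab["ls"] = 0.0
        return tab
    return pd.concat(rows, ignore_index=True)


def window_selection_stats(
    pv: PopulationVariants,
    subs: dict[str, pd.DataFrame],
    scmap: SiteClassMap,
    grid: WindowGrid,
    jc_correction: bool = False,
) -> pd.DataFrame:
    """Per-window pN/pS, dN/dS and per-site dS for every population.

    Counts use the codon-change classification (stop-involving changes
    excluded; multi-hit variants included with their reference-context
    class).  Ratios are (pN/LN)/(pS/LS) and (dN/LN)/(dS/LS); a window with
    a zero denominator count reports a missing ratio, never infinity.
    With ``jc_correction`` the per-site divergences are Jukes-Cantor
    corrected before the ratio.
    """
    frames = []
    for pop in pv.populations():
        df = pv.snps[pop]
        if "coding_class" not in df.columns:
            raise ValueError("run classify_polymorphisms before window_selection_stats")
        sites = _codon_window_sites(pv, scmap, grid, pop)
        sub = subs[pop]
        for scaf in grid.scaffold_lengths:
            n_win = grid.n_windows(scaf)
            block = sites[sites["scaffold"] == scaf].reset_index(drop=True)

            def _counts(table, pos_col, cls_col):
                res = {}
                mask_scaf = table["scaffold"] == scaf
                for label in ("synonymous", "nonsynonymous"):
                    m = mask_scaf & (table[cls_col] == label)
                    res[label] = np.bincount(
                        table.loc[m, pos_col].to_numpy() // grid.window_size,
                        minlength=n_win,
                    )[:n_win]
                return res

            p = _counts(df, "pos", "coding_class")
            d = _counts(sub, "pos", "classification")
            ln = block["ln"].to_numpy()
            ls = block["ls"].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                pn_rate = np.where(ln > 0, p["nonsynonymous"] / np.maximum(ln, 1e-300), np.nan)
                ps_rate = np.where(ls > 0, p["synonymous"] / np.maximum(ls, 1e-300), np.nan)
                dn_rate = np.where(ln > 0, d["nonsynonymous"] / np.maximum(ln, 1e-300), np.nan)
                ds_rate = np.where(ls > 0, d["synonymous"] / np.maximum(ls, 1e-300), np.nan)
                if jc_correction:
                    dn_rate = jc69(dn_rate)
                    ds_rate = jc69(ds_rate)
                pn_ps = np.where(
                    (p["synonymous"] > 0) & (ls > 0) & (ln > 0), pn_rate / ps_rate, np.nan
                )
                dn_ds = np.where(
                    (d["synonymous"] > 0) & (ls > 0) & (ln > 0), dn_rate / ds_rate, np.nan
                )
            frames.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "scaffold": scaf,
                        "start": block["start"],
                        "end": block["end"],
                        "pn": p["nonsynonymous"],
                        "ps": p["synonymous"],
                        "dn": d["nonsynonymous"],
                        "ds_count": d["synonymous"],
                        "ln": ln,
                        "ls": ls,
                        "pn_ps": pn_ps,
                        "dn_ds": dn_ds,
                        "ds": ds_rate,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def jc69(p: np.ndarray) -> np.ndarray:
    """Jukes-Cantor distance from a raw per-site divergence proportion."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(p < 0.75, -0.75 * np.log1p(-4.0 * p / 3.0), np.nan)


def alpha_from_counts(pn, ps, dn, ds) -> float:
    """MK point estimate alpha = 1 - (dS * pN) / (dN * pS); NaN if undefined."""
    if dn <= 0 or ps <= 0:
        return float("nan")
    return 1.0 - (ds * pn) / (dn * ps)


def mk_site_class_events(
    pv: PopulationVariants,
    subs: dict[str, pd.DataFrame],
    scmap: SiteClassMap,
    population: str,
    freq_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-gene MK event counts under the site-class scheme.

    Neutral class: four-fold degenerate sites (any change synonymous);
    selected class: second codon positions (any change nonsynonymous).
    Polymorphisms below the derived-allele-frequency floor are excluded
    when a floor is set (unpolarized SNPs fall back to the minor-allele
    frequency).  Returns one row per gene with pn, ps, dn, ds.
    """
    n_genes = len(scmap.gene_ids)
    counts = np.zeros((n_genes, 4))  # pn, ps, dn, ds

    df = pv.snps[population]
    if len(df):
        cid = np.array(
            [scmap.codon_id[s][p] for s, p in zip(df["scaffold"], df["pos"])]
        )
        ff = np.array(
            [scmap.fourfold[s][p] for s, p in zip(df["scaffold"], df["pos"])]
        )
        cls = np.array(
            [scmap.classes[s][p] for s, p in zip(df["scaffold"], df["pos"])]
        )
        valid = (cid >= 0) & scmap.codon_valid[np.clip(cid, 0, None)]
        if freq_floor > 0:
            der = df["derived_count"].to_numpy(dtype=float)
            n = df["n_hap"].to_numpy(dtype=float)
            minor = np.minimum(df["alt_count"], df["n_hap"] - df["alt_count"])
            freq = np.where(np.isnan(der), minor / n, der / n)
            valid &= freq >= freq_floor
        gene = np.where(valid, scmap.codon_gene[np.clip(cid, 0, None)], -1)
        for which, col in ((valid & (cls == POS2), 0), (valid & ff, 1)):
            np.add.at(counts[:, col], gene[which], 1)

    sub = subs[population]
    if len(sub):
        valid = (sub["codon_id"].to_numpy() >= 0) & scmap.codon_valid[
            np.clip(sub["codon_id"].to_numpy(), 0, None)
        ]
        gene = np.where(
            valid, scmap.codon_gene[np.clip(sub["codon_id"].to_numpy(), 0, None)], -1
        )
        is_pos2 = sub["site_class"].to_numpy() == POS2
        is_ff = sub["fourfold"].to_numpy().astype(bool)
        np.add.at(counts[:, 2], gene[valid & is_pos2], 1)
        np.add.at(counts[:, 3], gene[valid & is_ff], 1)

    out = pd.DataFrame(counts, columns=["pn", "ps", "dn", "ds"])
    out.insert(0, "gene_id", scmap.gene_ids)
    return out


def estimate_alpha(
    gene_events: pd.DataFrame,
    bootstrap_reps: int = 200,
    seed: int | None = None,
) -> dict:
    """Point estimate and percentile-bootstrap CI for the MK alpha.

    Resamples genes with replacement (preserving within-gene correlation of
    counts), recomputing alpha for each of ``bootstrap_reps`` resamples.
    Returns a dict with alpha, ci_low, ci_high, se, n_boot_valid and the
    pooled MKTable.  Alpha is missing when dN = 0 or pS = 0.
    """
    totals = gene_events[["pn", "ps", "dn", "ds"]].sum()
    alpha = alpha_from_counts(totals["pn"], totals["ps"], totals["dn"], totals["ds"])
    rng = np.random.default_rng(seed)
    mat = gene_events[["pn", "ps", "dn", "ds"]].to_numpy()
    n_genes = len(mat)
    boots = np.full(bootstrap_reps, np.nan)
    if n_genes and np.isfinite(alpha):
        for b in range(bootstrap_reps):
            pick = rng.integers(0, n_genes, size=n_genes)
            pn, ps, dn, ds = mat[pick].sum(axis=0)
            boots[b] = alpha_from_counts(pn, ps, dn, ds)
    valid = boots[np.isfinite(boots)]
    result = {
        "alpha": float(alpha),
        "ci_low": float(np.percentile(valid, 2.5)) if len(valid) else float("nan"),
        "ci_high": float(np.percentile(valid, 97.5)) if len(valid) else float("nan"),
        "se": float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
        "n_boot_valid": int(len(valid)),
        "table": MKTable(
            scope="population",
            pn=float(totals["pn"]),
            ps=float(totals["ps"]),
            dn=float(totals["dn"]),
            ds=float(totals["ds"]),
            ln=float("nan"),
            ls=float("nan"),
        ),
    }
    return result


def population_mk_report(
    pv: PopulationVariants,
    subs: dict[str, pd.DataFrame],
    scmap: SiteClassMap,
    bootstrap_reps: int = 200,
    seed: int | None = None,
    freq_floor: float = 0.0,
) -> pd.DataFrame:
    """MK alpha with bootstrap CI for every population (site-class scheme)."""
    rows = []
    # site totals for the report: callable 4D (LS) and pos2 (LN) sites
    for i, pop in enumerate(pv.populations()):
        events = mk_site_class_events(pv, subs, scmap, pop, freq_floor)
        res = estimate_alpha(
            events,
            bootstrap_reps=bootstrap_reps,
            seed=None if seed is None else seed + i,
        )
        ln = ls = 0
        for scaf in scmap.scaffold_names:
            call = pv.callable_mask[pop][scaf]
            ln += int((call & (scmap.classes[scaf] == POS2)).sum())
            ls += int((call & scmap.fourfold[scaf]).sum())
        rows.append(
            {
                "population": pop,
                "pn": res["table"].pn,
                "ps": res["table"].ps,
                "dn": res["table"].dn,
                "ds": res["table"].ds,
                "ln": ln,
                "ls": ls,
                "alpha": res["alpha"],
                "alpha_ci_low": res["ci_low"],
                "alpha_ci_high": res["ci_high"],
                "alpha_se": res["se"],
                "bootstrap_reps": bootstrap_reps,
                "freq_floor": freq_floor,
            }
        )
    return pd.DataFrame(rows)
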