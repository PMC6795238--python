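"""SNP inclusion filters and per-population allele counts.

Implements the inclusion rules applied before any diversity or selection
statistic: a per-population depth rule (every individual of the population
covered at least ``min_depth`` times at the site), site quality (variant
QUAL and INFO/MQ thresholds), and a biallelic + genotyping-rate rule
(strictly more than ``min_callrate`` of individuals genotyped).  The depth
rule is evaluated per population -- an individual outside the population
cannot veto a site for it -- while quality and call-rate act on the record.

Alongside the per-population SNP tables the module maintains a per-site
callability mask: monomorphic callable sites enter diversity denominators
through this mask rather than through the SNP list.  Sites dropped by any
filter are removed from the mask as well, so numerators and denominators
stay consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("leptidiv")

MISSING_DP = -1


@dataclass
class VariantDataset:
    """In-memory multi-sample variant table (one ALT recorded per row).

    ``gt`` is (n_variants, n_samples, 2) with allele indices and -1 for
    missing calls; ``dp`` is per-sample depth with -1 for missing.  Records
    with more than one ALT keep their first ALT for bookkeeping and are
    flagged multiallelic (they are dropped by the biallelic filter).
    """

    samples: list[str]
    scaffold: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    mq: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    multiallelic: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def is_snp(self) -> np.ndarray:
        ref_len = np.char.str_len(self.ref.astype(str))
        alt_len = np.char.str_len(self.alt.astype(str))
        return (ref_len == 1) & (alt_len == 1)


@dataclass
class PopulationVariants:
    """Filtered per-population SNPs plus callability masks and QC tallies.

    ``snps`` maps population -> DataFrame with columns scaffold, pos, ref,
    alt, alt_count, n_hap (callable haplotypes), derived_count (NaN when the
    site could not be polarized), qual, mq.  ``callable_mask`` maps
    population -> scaffold -> boolean array over all sites.
    """

    snps: dict[str, pd.DataFrame]
    callable_mask: dict[str, dict[str, np.ndarray]]
    qc: dict = field(default_factory=dict)

    def populations(self) -> list[str]:
        return list(self.snps)

    def n_callable(self, population: str, scaffold: str) -> int:
        return int(self.callable_mask[population][scaffold].sum())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_vcf(path) -> VariantDataset:
    """Read a VCF (v4.x, plain text or bgzipped) into a VariantDataset."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n_samp = len(samples)
    scaffold, pos, ref, alt, qual, mq, multi = [], [], [], [], [], [], []
    gt_rows, dp_rows = [], []
    for var in vcf:
        scaffold.append(var.CHROM)
        pos.append(var.start)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else "")
        qual.append(var.QUAL if var.QUAL is not None else np.nan)
        mq_val = var.INFO.get("MQ")
        mq.append(float(mq_val) if mq_val is not None else np.nan)
        multi.append(len(var.ALT) > 1)
        geno = np.array(var.genotypes, dtype=np.int16)[:, :2]
        gt_rows.append(geno)
        dp = var.format("DP")
        if dp is None:
            dp_rows.append(np.full(n_samp, MISSING_DP, dtype=np.int32))
        else:
            dp = dp.astype(np.int32).reshape(n_samp)
            dp[dp < 0] = MISSING_DP
            dp_rows.append(dp)
    vcf.close()
    n_var = len(pos)
    return VariantDataset(
        samples=samples,
        scaffold=np.asarray(scaffold, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=float),
        mq=np.asarray(mq, dtype=float),
        gt=(
            np.stack(gt_rows)
            if gt_rows
            else np.empty((0, n_samp, 2), dtype=np.int16)
        ),
        dp=(
            np.stack(dp_rows) if dp_rows else np.empty((0, n_samp), dtype=np.int32)
        ),
        multiallelic=np.asarray(multi, dtype=bool),
    )


def read_manifest(path) -> dict[str, str]:
    """Read a sample -> population manifest TSV (columns sample_id, population)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "population"} <= set(df.columns):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["sample_id", "population"]
        )
    return dict(zip(df["sample_id"].astype(str), df["population"].astype(str)))


def population_sample_indices(
    ds: VariantDataset, manifest: dict[str, str]
) -> dict[str, np.ndarray]:
    missing = [s for s in ds.samples if s not in manifest]
    if missing:
        raise ValueError(f"samples absent from manifest: {missing}")
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(ds.samples):
        pops.setdefault(manifest[s], []).append(i)
    return {p: np.asarray(idx, dtype=np.int64) for p, idx in sorted(pops.items())}


# ---------------------------------------------------------------------------
# Filter predicates (each returns a boolean retain-mask over records)
# ---------------------------------------------------------------------------


def filter_depth(
    ds: VariantDataset, sample_idx: np.ndarray, min_depth: int = 2
) -> np.ndarray:
    """Retain a site iff every listed individual has DP >= min_depth.

    Missing DP counts as zero coverage.  ``min_depth == 0`` retains all.
    """
    if ds.dp.size and (ds.dp == MISSING_DP).all():
        raise ValueError("FORMAT/DP absent from all records; depth filter needs DP")
    if min_depth <= 0:
        return np.ones(ds.n_variants, dtype=bool)
    dp = ds.dp[:, sample_idx]
    return (np.where(dp == MISSING_DP, 0, dp) >= min_depth).all(axis=1)


def filter_quality(
    ds: VariantDataset,
    min_qual: float = 15.0,
    min_mq: float = 20.0,
    combine: str = "or",
) -> np.ndarray:
    """Retain a site unless it fails the QUAL/MQ thresholds.

    Thresholds are exclusive (QUAL < min_qual fails; QUAL == min_qual
    passes).  ``combine='or'`` drops a record failing either criterion (the
    conservative reading); ``combine='and'`` drops only records failing
    both.  Missing QUAL or MQ counts as failing that criterion.
    """
    bad_qual = ~(ds.qual >= min_qual)
    bad_mq = ~(ds.mq >= min_mq)
    if combine == "or":
        return ~(bad_qual | bad_mq)
    if combine == "and":
        return ~(bad_qual & bad_mq)
    raise ValueError(f"combine must be 'or' or 'and', got {combine!r}")


def filter_biallelic_callrate(
    ds: VariantDataset,
    sample_idx: np.ndarray | None = None,
    min_callrate: float = 0.9,
) -> np.ndarray:
    """Retain biallelic SNP records with genotyping rate strictly > min_callrate."""
    idx = sample_idx if sample_idx is not None else np.arange(len(ds.samples))
    gt = ds.gt[:, idx, :]
    called = (gt >= 0).all(axis=2)
    callrate = called.mean(axis=1) if len(idx) else np.ones(ds.n_variants)
    return ds.is_snp() & ~ds.multiallelic & (callrate > min_callrate)


# ---------------------------------------------------------------------------
# Combined application
# ---------------------------------------------------------------------------

DROP_REASONS = ("multiallelic_or_non_snp", "quality", "callrate", "depth")


def apply_filters(
    ds: VariantDataset,
    manifest: dict[str, str],
    scaffold_lengths: dict[str, int],
    n_mask: dict[str, np.ndarray] | None = None,
    min_depth: int = 2,
    min_qual: float = 15.0,
    min_mq: float = 20.0,
    min_callrate: float = 0.9,
    qual_mq_combine: str = "or",
) -> PopulationVariants:
    """Apply all inclusion filters and build per-population SNP tables.

    Filters are pure predicates over the record set, so their application
    order cannot change the retained set; drop *reasons* are attributed in
    the fixed order multiallelic/quality/callrate/depth for QC reporting.
    Every filtered-out variant position is removed from the population's
    callability mask; assembly gaps (``n_mask``) are never callable.
    """
    pops = population_sample_indices(ds, manifest)
    q_mask = filter_quality(ds, min_qual, min_mq, qual_mq_combine)
    b_mask = filter_biallelic_callrate(ds, None, min_callrate)
    ba_only = ds.is_snp() & ~ds.multiallelic

    snps: dict[str, pd.DataFrame] = {}
    callable_mask: dict[str, dict[str, np.ndarray]] = {}
    qc: dict = {"populations": {}, "thresholds": {
        "min_depth": min_depth, "min_qual": min_qual, "min_mq": min_mq,
        "min_callrate": min_callrate, "qual_mq_combine": qual_mq_combine,
    }}

    scaf_codes, scaf_uniques = pd.factorize(pd.Series(ds.scaffold, dtype=object))

    for pop, idx in pops.items():
        if 2 * len(idx) < 2:
            raise ValueError(f"population {pop} has fewer than 2 haplotypes")
        d_mask = filter_depth(ds, idx, min_depth)
        retained = q_mask & b_mask & d_mask

        reason = np.full(ds.n_variants, "retained", dtype=object)
        reason[~d_mask] = "depth"
        reason[ba_only & ~b_mask] = "callrate"
        reason[~q_mask] = "quality"
        reason[~ba_only] = "multiallelic_or_non_snp"
        reason[retained] = "retained"
        counts = pd.Series(reason).value_counts().to_dict()
        qc["populations"][pop] = {
            "input_records": int(ds.n_variants),
            "retained": int(retained.sum()),
            "dropped": {
                r: int(counts.get(r, 0)) for r in DROP_REASONS
            },
        }

        mask = {}
        for scaf, length in scaffold_lengths.items():
            m = np.ones(length, dtype=bool)
            if n_mask is not None and scaf in n_mask:
                m &= ~n_mask[scaf]
            mask[scaf] = m
        dropped_idx = np.flatnonzero(~retained)
        for vi in dropped_idx:
            scaf = ds.scaffold[vi]
            if scaf in mask:
                mask[scaf][ds.pos[vi]] = False
        callable_mask[pop] = mask

        gt = ds.gt[:, idx, :]
        called = gt >= 0
        n_hap = called.sum(axis=(1, 2))
        alt_count = ((gt == 1) & called).sum(axis=(1, 2))
        poly = retained & (alt_count > 0) & (alt_count < n_hap)
        fixed_alt = retained & (n_hap > 0) & (alt_count == n_hap)

        snps[pop] = pd.DataFrame(
            {
                "scaffold": ds.scaffold[poly],
                "pos": ds.pos[poly],
                "ref": ds.ref[poly],
                "alt": ds.alt[poly],
                "alt_count": alt_count[poly],
                "n_hap": n_hap[poly],
                "derived_count": np.full(int(poly.sum()), np.nan),
                "qual": ds.qual[poly],
                "mq": ds.mq[poly],
            }
        ).reset_index(drop=True)
        qc["populations"][pop]["segregating"] = int(poly.sum())
        qc["populations"][pop]["fixed_alt"] = int(fixed_alt.sum())

        # retained records monomorphic within the population contribute to
        # the callability mask only; fixed-ALT records are kept separately
        # for substitution calling
        fa = pd.DataFrame(
            {
                "scaffold": ds.scaffold[fixed_alt],
                "pos": ds.pos[fixed_alt],
                "ref": ds.ref[fixed_alt],
                "alt": ds.alt[fixed_alt],
                "n_hap": n_hap[fixed_alt],
            }
        ).reset_index(drop=True)
        snps[pop].attrs["fixed_alt"] = fa

    return PopulationVariants(snps=snps, callable_mask=callable_mask, qc=qc)


def allele_counts(
    pv: PopulationVariants, ancestral: dict[str, np.ndarray]
) -> PopulationVariants:
    """Polarize SNPs against a per-site ancestral allele (base codes).

    ``ancestral`` maps scaffold -> encoded base array aligned to reference
    coordinates (e.g. an outgroup sequence).  The derived count is the
    number of haplotypes carrying the non-ancestral allele.  Sites whose
    ancestral base matches neither REF nor ALT (or is N) keep a missing
    derived count, are excluded from polarized analyses and counted in QC.
    """
    from .annotation_sites import BASES

    base_to_code = {b: i for i, b in enumerate(BASES)}
    qc_unpolarized = {}
    for pop, df in pv.snps.items():
        if not len(df):
            qc_unpolarized[pop] = 0
            continue
        anc_codes = np.array(
            [ancestral[s][p] for s, p in zip(df["scaffold"], df["pos"])],
            dtype=np.int16,
        )
        ref_codes = np.array([base_to_code.get(r, 4) for r in df["ref"]])
        alt_codes = np.array([base_to_code.get(a, 4) for a in df["alt"]])
        derived = np.full(len(df), np.nan)
        is_ref = (anc_codes == ref_codes) & (anc_codes < 4)
        is_alt = (anc_codes == alt_codes) & (anc_codes < 4)
        derived[is_ref] = df["alt_count"].to_numpy()[is_ref]
        derived[is_alt] = (df["n_hap"] - df["alt_count"]).to_numpy()[is_alt]
        df["derived_count"] = derived
        qc_unpolarized[pop] = int((~is_ref & ~is_alt).sum())
    pv.qc["unpolarized_snps"] = qc_unpolarized
    return pv


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_population_variants(pv: PopulationVariants, outdir) -> None:
    """Write per-population SNP TSVs and callability BEDs."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pop, df in pv.snps.items():
        df.to_csv(outdir / f"snps.{pop}.tsv", sep="\t", index=False)
        with open(outdir / f"callable.{pop}.bed", "w") as fh:
            for scaf, mask in pv.callable_mask[pop].items():
                edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
                bounds = np.concatenate(([0], edges, [len(mask)]))
                for s, e in zip(bounds[:-1], bounds[1:]):
                    if mask[s]:
                        fh.write(f"{scaf}\t{s}\t{e}\n")
    with open(outdir / "filter_qc.json", "w") as fh:
        json.dump(pv.qc, fh, indent=2, sort_keys=True)
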