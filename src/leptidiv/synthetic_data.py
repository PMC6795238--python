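"""Synthetic genomes, gene models, polymorphism, divergence and rho tracks.

The generator emulates the data regime of a multi-population butterfly
resequencing study so that every downstream estimator can be validated
without any external download: six populations of ten diploid individuals,
per-population neutral diversity spanning roughly 0.0016-0.0031 per site,
reduced diversity at selected (first/second codon position) sites, regional
mutation-rate heterogeneity shared between polymorphism and divergence, a
GC-content contrast between coding (~45%) and noncoding (~32%) sequence,
per-window recombination-rate (rho) tracks, and missing/low-depth genotype
artifacts to exercise the inclusion filters.

The model is deliberately site-independent: each eligible site segregates
with probability theta_local * H(n-1) (so realized per-site theta_pi equals
the configured theta in expectation), the derived-allele count i is drawn
with probability proportional to 1/i (the standard neutral site-frequency
spectrum), and genotypes come from random haplotype pairing.  No coalescent
tree or linkage structure is simulated; linked selection enters
phenomenologically as a per-window diversity multiplier coupled positively
to rho and negatively to gene density, which is all the downstream
regression stage needs.  Divergence is placed on the outgroup branch at
Poisson-thin rates sharing the same per-window mutation multiplier, with an
extra adaptive component at nonsynonymous (first/second position) sites so
the true adaptive fraction alpha is known exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_sites import (
    GENIC_NC,
    INTERGENIC,
    INTRON,
    MASKED,
    POS1,
    POS2,
    POS3,
    BASES,
    GeneModel,
    GenomeBundle,
    SiteClassMap,
    STOP_CODON,
    WindowGrid,
    build_site_class_map,
    decode_seq,
)
from .variant_filters import VariantDataset

logger = logging.getLogger("leptidiv")

STOP_INDICES = np.flatnonzero(STOP_CODON)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe the emulated study design: six populations x ten
    diploids with neutral theta values bracketing 0.0016-0.0031 per site
    (three conspecific populations at the top of the range, one
    intermediate, two at the bottom), a selected-site diversity factor of
    0.3, coding/noncoding GC targets of 0.45/0.32, shallow divergence
    (0.02 substitutions per neutral site) with an adaptive nonsynonymous
    fraction of 0.12, log-normal per-window mutation-rate heterogeneity,
    and mild coverage artifacts.
    """

    seed: int = 0
    n_scaffolds: int = 10
    scaffold_length: int = 200_000
    n_genes_per_scaffold: int = 8
    exon_length_dist: tuple[float, float] = (285.0, 60.0)
    introns_per_gene: int = 3
    intron_length_dist: tuple[float, float] = (400.0, 100.0)
    populations: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            ("LsSwe", 10, 0.0031),
            ("LsKaz", 10, 0.0031),
            ("LsSpa", 10, 0.0031),
            ("LrSpa", 10, 0.0024),
            ("LjKaz", 10, 0.0016),
            ("LjIre", 10, 0.0016),
        ]
    )
    selected_site_theta_factor: float = 0.3
    divergence_rate_neutral: float = 0.02
    adaptive_nonsyn_fraction: float = 0.12
    mutation_rate_multiplier_sd: float = 0.3
    coding_gc_target: float = 0.45
    noncoding_gc_target: float = 0.32
    rho_profile: tuple[float, float] = (0.04, 0.02)
    linked_selection_coupling: tuple[float, float] = (0.15, -0.15)
    selection_efficiency_coupling: float = 0.5
    missing_genotype_rate: float = 0.02
    low_depth_rate: float = 0.01
    mispolarization_rate: float = 0.0
    mean_depth: float = 12.0
    window_size: int = 100_000

    def validate(self) -> None:
        for name, val in (
            ("n_scaffolds", self.n_scaffolds),
            ("scaffold_length", self.scaffold_length),
            ("window_size", self.window_size),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.n_genes_per_scaffold < 0:
            raise ValueError("n_genes_per_scaffold must be >= 0")
        if not 0 < self.selected_site_theta_factor <= 1:
            raise ValueError("selected_site_theta_factor must be in (0, 1]")
        if not 0 <= self.adaptive_nonsyn_fraction < 1:
            raise ValueError("adaptive_nonsyn_fraction must be in [0, 1)")
        for name, frac in (
            ("coding_gc_target", self.coding_gc_target),
            ("noncoding_gc_target", self.noncoding_gc_target),
            ("missing_genotype_rate", self.missing_genotype_rate),
            ("low_depth_rate", self.low_depth_rate),
            ("mispolarization_rate", self.mispolarization_rate),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.divergence_rate_neutral < 0:
            raise ValueError("divergence_rate_neutral must be >= 0")
        for name, n, theta in self.populations:
            if n < 1:
                raise ValueError(f"population {name} needs >= 1 diploid (2 haplotypes)")
            if theta < 0:
                raise ValueError(f"population {name} has negative theta")


@dataclass
class TruthRecord:
    """Ground truth written alongside the outputs for parameter recovery."""

    windows: pd.DataFrame
    params: dict


# ---------------------------------------------------------------------------
# Reference genome and gene models
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.int8)


_CODING_P_CACHE: dict[float, float] = {}


def _adjusted_coding_p(gc_target: float) -> float:
    """Per-base GC probability whose sense-codon distribution hits gc_target.

    Excluding stop codons (which are AT-rich) biases rejection-sampled
    coding sequence toward GC, so the raw per-base probability is adjusted
    by solving E[GC | sense codon](p) = gc_target.
    """
    if gc_target in _CODING_P_CACHE:
        return _CODING_P_CACHE[gc_target]
    from scipy.optimize import brentq

    codons = np.arange(64)
    digits = np.stack([codons // 16, codons // 4 % 4, codons % 4], axis=1)
    n_gc = ((digits == 1) | (digits == 2)).sum(axis=1)
    sense = ~STOP_CODON

    def realized(p):
        w = (p / 2) ** n_gc * ((1 - p) / 2) ** (3 - n_gc)
        w = w * sense
        return (w * n_gc).sum() / (3 * w.sum())

    lo, hi = 1e-3, 1 - 1e-3
    if realized(lo) >= gc_target:
        p = lo
    elif realized(hi) <= gc_target:
        p = hi
    else:
        p = float(brentq(lambda q: realized(q) - gc_target, lo, hi, xtol=1e-10))
    _CODING_P_CACHE[gc_target] = p
    return p


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> np.ndarray:
    """Random coding sequence: no internal stop codons, terminal stop appended."""
    gc = _adjusted_coding_p(gc)
    codes = _random_bases(rng, 3 * n_codons, gc).reshape(-1, 3)
    idx = codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]
    bad = np.flatnonzero(STOP_CODON[idx])
    while len(bad):
        codes[bad] = _random_bases(rng, 3 * len(bad), gc).reshape(-1, 3)
        idx = codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]
        bad = np.flatnonzero(STOP_CODON[idx])
    stop = STOP_INDICES[rng.integers(len(STOP_INDICES))]
    codes[-1] = [stop // 16, stop // 4 % 4, stop % 4]
    return codes.reshape(-1)


def generate_reference(config: SimulationConfig) -> GenomeBundle:
    """Generate the reference FASTA sequences and gene models.

    Genes are placed without overlap, on random strands, with CDS length
    always a multiple of three (terminal stop included) and no in-frame
    stop codons except the terminal one.  Raises a sizing error when the
    requested genes cannot fit in a scaffold.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scaffolds: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    exon_mu, exon_sd = config.exon_length_dist
    intron_mu, intron_sd = config.intron_length_dist
    min_gap = 100
    for s in range(config.n_scaffolds):
        name = f"scaffold_{s + 1}"
        seq = _random_bases(rng, config.scaffold_length, config.noncoding_gc_target)
        spans = []
        structures = []
        for g in range(config.n_genes_per_scaffold):
            n_exons = config.introns_per_gene + 1
            exon_len = np.maximum(
                30, np.round(rng.normal(exon_mu, exon_sd, n_exons)).astype(int)
            )
            total = exon_len.sum()
            exon_len[-1] += (3 - total % 3) % 3
            intron_len = (
                np.maximum(
                    50,
                    np.round(
                        rng.normal(intron_mu, intron_sd, config.introns_per_gene)
                    ).astype(int),
                )
                if config.introns_per_gene
                else np.empty(0, int)
            )
            spans.append(int(exon_len.sum() + intron_len.sum()))
            structures.append((exon_len, intron_len))
        total_span = sum(spans)
        n_genes = config.n_genes_per_scaffold
        free = config.scaffold_length - total_span - min_gap * (n_genes + 1)
        if n_genes and free < 0:
            raise ValueError(
                "gene layout infeasible: "
                f"{n_genes} genes spanning {total_span} bp plus minimum gaps "
                f"exceed scaffold_length {config.scaffold_length}"
            )
        if n_genes:
            cuts = np.sort(rng.random(n_genes)) * free
            gaps = np.diff(np.concatenate(([0.0], cuts, [float(free)])))
            gaps = np.round(gaps).astype(int) + min_gap
            cursor = 0
            for g in range(n_genes):
                cursor += gaps[g]
                exon_len, intron_len = structures[g]
                start = cursor
                segments = []
                pos = start
                for i, el in enumerate(exon_len):
                    segments.append((pos, pos + int(el)))
                    pos += int(el)
                    if i < len(intron_len):
                        pos += int(intron_len[i])
                cursor = pos
                strand = "+" if rng.random() < 0.5 else "-"
                n_codons = exon_len.sum() // 3
                cds = _random_cds(rng, int(n_codons), config.coding_gc_target)
                if strand == "+":
                    offset = 0
                    for seg_s, seg_e in segments:
                        seq[seg_s:seg_e] = cds[offset : offset + seg_e - seg_s]
                        offset += seg_e - seg_s
                else:
                    offset = 0
                    for seg_s, seg_e in reversed(segments):
                        chunk = cds[offset : offset + seg_e - seg_s]
                        seq[seg_s:seg_e] = (3 - chunk)[::-1]
                        offset += seg_e - seg_s
                genes.append(
                    GeneModel(
                        gene_id=f"gene_{s + 1}_{g + 1}",
                        scaffold=name,
                        strand=strand,
                        cds_segments=segments,
                        phase=0,
                    )
                )
        scaffolds[name] = seq
    return GenomeBundle(scaffolds=scaffolds, genes=genes)


# ---------------------------------------------------------------------------
# Window-level multipliers shared by polymorphism and divergence
# ---------------------------------------------------------------------------


def _window_profiles(config: SimulationConfig, bundle: GenomeBundle):
    """Per-window mutation multiplier, rho, gene density and coupling terms.

    The mutation multiplier is log-normal (normalized to mean 1 across
    windows); the linked-selection diversity multiplier is
    exp(b_rho * z(rho) + b_gd * z(gene density)), also normalized to mean 1;
    the per-window selected-site factor f_w couples selection efficiency to
    local diversity, f_w = f * L_w^(-kappa) clipped to (0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    grid = WindowGrid(config.window_size, bundle.scaffold_lengths())
    rows = []
    for scaf in sorted(bundle.scaffolds):
        for start, end in grid.windows(scaf):
            rows.append((scaf, start, end))
    win = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    n_win = len(win)

    mult = rng.lognormal(0.0, config.mutation_rate_multiplier_sd, n_win)
    mult /= mult.mean()

    rho_mu, rho_sd = config.rho_profile
    rho = np.maximum(rng.normal(rho_mu, rho_sd, n_win), 0.0)

    # gene density per window from the gene layout
    gd = np.zeros(n_win)
    index = {
        (r.scaffold, r.start): i for i, r in win.iterrows()
    }
    coding = {scaf: np.zeros(length, bool) for scaf, length in bundle.scaffold_lengths().items()}
    for gene in bundle.genes:
        for s, e in gene.cds_segments:
            coding[gene.scaffold][s:e] = True
    for i, r in win.iterrows():
        gd[i] = coding[r.scaffold][r.start : r.end].mean()

    def zscore(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    b_rho, b_gd = config.linked_selection_coupling
    linked = np.exp(b_rho * zscore(rho) + b_gd * zscore(gd))
    linked /= linked.mean()

    kappa = config.selection_efficiency_coupling
    f = config.selected_site_theta_factor
    with np.errstate(divide="ignore"):
        f_w = np.clip(f * np.where(linked > 0, linked, 1.0) ** (-kappa), 1e-6, 1.0)

    win["mut_multiplier"] = mult
    win["rho"] = rho
    win["gene_density"] = gd
    win["linked_multiplier"] = linked
    win["selected_factor"] = f_w
    _ = index
    return win, grid


def _site_rate_factors(
    scmap: SiteClassMap, scaf: str, win: pd.DataFrame, grid: WindowGrid, kind: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-site rate = class factor x window multiplier (x linked multiplier)."""
    cls = scmap.classes[scaf]
    ff = scmap.fourfold[scaf]
    length = len(cls)
    sub = win[win["scaffold"] == scaf].sort_values("start")
    widx = np.minimum(np.arange(length) // grid.window_size, len(sub) - 1)
    mult = sub["mut_multiplier"].to_numpy()[widx]
    f_w = sub["selected_factor"].to_numpy()[widx]
    factor = np.ones(length)
    selected = (cls == POS1) | (cls == POS2)
    factor[selected] = f_w[selected]
    pos3_nonff = (cls == POS3) & ~ff
    factor[pos3_nonff] = (1.0 + f_w[pos3_nonff]) / 2.0
    # masked (stop codons, conflicts) and genic noncoding evolve neutrally;
    # N sites are ineligible
    rate = factor * mult
    if kind == "poly":
        linked = sub["linked_multiplier"].to_numpy()[widx]
        rate = rate * linked
    elif kind == "div":
        a = config.adaptive_nonsyn_fraction
        if a > 0:
            boost = np.ones(length)
            boost[selected] = 1.0 / (1.0 - a)
            rate = rate * boost
    rate[scmap.n_mask[scaf]] = 0.0
    return rate


# ---------------------------------------------------------------------------
# Polymorphism
# ---------------------------------------------------------------------------


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def simulate_polymorphisms(
    config: SimulationConfig,
    bundle: GenomeBundle,
    scmap: SiteClassMap | None = None,
    profiles: pd.DataFrame | None = None,
) -> tuple[VariantDataset, TruthRecord]:
    """Simulate segregating sites for every population and emit genotypes.

    Each eligible site segregates in population p with probability
    theta_local * H(n_p - 1); the derived-allele count follows the neutral
    1/i spectrum; derived alleles are assigned to a uniform random subset
    of haplotypes and haplotypes pair into diploids.  Sites may segregate
    in several populations (sharing one ALT allele).  QUAL, INFO/MQ and
    FORMAT GT:DP are populated so the filter stage is fully exercised.
    """
    config.validate()
    for name, n, _ in config.populations:
        if 2 * n < 2:
            raise ValueError(f"population {name}: need >= 2 haplotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if scmap is None:
        scmap = build_site_class_map(bundle)
    if profiles is None:
        profiles, grid = _window_profiles(config, bundle)
    else:
        grid = WindowGrid(config.window_size, bundle.scaffold_lengths())

    pop_names = [p[0] for p in config.populations]
    n_dip = {p[0]: p[1] for p in config.populations}
    thetas = {p[0]: p[2] for p in config.populations}
    samples = [
        f"{pop}_{i + 1:02d}" for pop in pop_names for i in range(n_dip[pop])
    ]
    sample_pop_slices = {}
    cursor = 0
    for pop in pop_names:
        sample_pop_slices[pop] = slice(cursor, cursor + n_dip[pop])
        cursor += n_dip[pop]
    n_samples = len(samples)

    sfs_cdf = {}
    for pop in pop_names:
        n_hap = 2 * n_dip[pop]
        if n_hap >= 2:
            w = 1.0 / np.arange(1, n_hap)
            sfs_cdf[pop] = np.cumsum(w / w.sum())

    rec_scaffold, rec_pos, rec_ref, rec_alt = [], [], [], []
    gt_blocks = []
    truth_class_rows = []

    for scaf in sorted(bundle.scaffolds):
        seq = bundle.scaffolds[scaf]
        length = len(seq)
        seg = {}
        any_seg = np.zeros(length, dtype=bool)
        rate = _site_rate_factors(scmap, scaf, profiles, grid, "poly", config)
        for pop in pop_names:
            theta = thetas[pop]
            n_hap = 2 * n_dip[pop]
            if theta <= 0 or n_hap < 2:
                seg[pop] = np.zeros(length, dtype=bool)
                continue
            p_seg = np.minimum(theta * _harmonic(n_hap) * rate, 0.99)
            seg[pop] = rng.random(length) < p_seg
            any_seg |= seg[pop]
        positions = np.flatnonzero(any_seg)
        if not len(positions):
            continue
        ref_codes = seq[positions]
        shift = rng.integers(1, 4, size=len(positions)).astype(np.int8)
        alt_codes = ((ref_codes + shift) % 4).astype(np.int8)

        gt = np.zeros((len(positions), n_samples, 2), dtype=np.int16)
        for pop in pop_names:
            mask = seg[pop][positions]
            rows = np.flatnonzero(mask)
            if not len(rows):
                continue
            n_hap = 2 * n_dip[pop]
            u = rng.random(len(rows))
            i_der = np.searchsorted(sfs_cdf[pop], u) + 1
            r = rng.random((len(rows), n_hap))
            rank = r.argsort(axis=1).argsort(axis=1)
            derived = rank < i_der[:, None]
            hap = derived.astype(np.int16).reshape(len(rows), n_dip[pop], 2)
            sl = sample_pop_slices[pop]
            gt[rows, sl.start : sl.stop, :] = hap
        rec_scaffold.append(np.full(len(positions), scaf, dtype=object))
        rec_pos.append(positions)
        rec_ref.append(ref_codes)
        rec_alt.append(alt_codes)
        gt_blocks.append(gt)

    if rec_pos:
        scaffold_arr = np.concatenate(rec_scaffold)
        pos_arr = np.concatenate(rec_pos)
        ref_arr = np.array([BASES[c] for c in np.concatenate(rec_ref)], dtype=object)
        alt_arr = np.array([BASES[c] for c in np.concatenate(rec_alt)], dtype=object)
        gt_arr = np.concatenate(gt_blocks)
    else:
        scaffold_arr = np.empty(0, dtype=object)
        pos_arr = np.empty(0, dtype=np.int64)
        ref_arr = np.empty(0, dtype=object)
        alt_arr = np.empty(0, dtype=object)
        gt_arr = np.empty((0, n_samples, 2), dtype=np.int16)

    n_var = len(pos_arr)
    qual = np.round(rng.uniform(50.0, 2000.0, n_var), 1)
    mq = np.round(np.clip(rng.normal(55.0, 3.0, n_var), 20.0, 60.0), 2)
    dp = rng.poisson(config.mean_depth, (n_var, n_samples)).astype(np.int32)
    dp = np.maximum(dp, 2)

    ds = VariantDataset(
        samples=samples,
        scaffold=scaffold_arr,
        pos=pos_arr,
        ref=ref_arr,
        alt=alt_arr,
        qual=qual,
        mq=mq,
        gt=gt_arr,
        dp=dp,
        multiallelic=np.zeros(n_var, dtype=bool),
    )
    truth = TruthRecord(
        windows=profiles.copy(),
        params={
            "seed": config.seed,
            "populations": {p: {"n_diploid": n_dip[p], "theta_neutral": thetas[p]} for p in pop_names},
            "selected_site_theta_factor": config.selected_site_theta_factor,
            "divergence_rate_neutral": config.divergence_rate_neutral,
            "true_alpha": config.adaptive_nonsyn_fraction,
        },
    )
    _ = truth_class_rows
    return ds, truth


# ---------------------------------------------------------------------------
# Divergence (outgroup branch)
# ---------------------------------------------------------------------------


def simulate_divergence(
    config: SimulationConfig,
    bundle: GenomeBundle,
    scmap: SiteClassMap | None = None,
    profiles: pd.DataFrame | None = None,
    variants: VariantDataset | None = None,
) -> tuple[dict[str, np.ndarray], TruthRecord]:
    """Place fixed differences on the outgroup sequence.

    Substitution probability per site is divergence_rate_neutral x class
    factor x the same per-window mutation multiplier used for
    polymorphism; nonsynonymous (first/second position) sites get the
    extra adaptive rate a/(1-a).  With a nonzero mispolarization rate,
    that fraction of polymorphic sites has its outgroup base set to the
    derived (ALT) allele.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    if scmap is None:
        scmap = build_site_class_map(bundle)
    if profiles is None:
        profiles, grid = _window_profiles(config, bundle)
    else:
        grid = WindowGrid(config.window_size, bundle.scaffold_lengths())

    outgroup = {}
    for scaf in sorted(bundle.scaffolds):
        seq = bundle.scaffolds[scaf].copy()
        if config.divergence_rate_neutral > 0:
            rate = _site_rate_factors(scmap, scaf, profiles, grid, "div", config)
            # one hit at most per site: substitution probability is linear in
            # the rate, so divergence counts stay exactly proportional to the
            # configured class rates (the regime the MK estimator assumes)
            p_sub = np.minimum(config.divergence_rate_neutral * rate, 1.0)
            hit = np.flatnonzero((rng.random(len(seq)) < p_sub) & (seq < 4))
            if len(hit):
                shift = rng.integers(1, 4, size=len(hit)).astype(np.int8)
                seq[hit] = (seq[hit] + shift) % 4
        outgroup[scaf] = seq

    if config.mispolarization_rate > 0 and variants is not None and variants.n_variants:
        flip = rng.random(variants.n_variants) < config.mispolarization_rate
        base_code = {b: i for i, b in enumerate(BASES)}
        for vi in np.flatnonzero(flip):
            scaf = variants.scaffold[vi]
            outgroup[scaf][variants.pos[vi]] = base_code.get(
                str(variants.alt[vi]), 4
            )

    truth = TruthRecord(
        windows=profiles.copy(),
        params={"true_alpha": config.adaptive_nonsyn_fraction},
    )
    return outgroup, truth


# ---------------------------------------------------------------------------
# Recombination track and coverage artifacts
# ---------------------------------------------------------------------------


def simulate_rho_track(
    config: SimulationConfig, profiles: pd.DataFrame | None = None,
    bundle: GenomeBundle | None = None,
) -> pd.DataFrame:
    """Emit the rho track as BED-like intervals tiling each scaffold.

    One interval per window, carrying the per-window rho already drawn for
    the profiles (sd parameter 0 gives a constant track).  Intervals tile
    each scaffold exactly, without gaps or overlaps.
    """
    config.validate()
    if profiles is None:
        if bundle is None:
            bundle = generate_reference(config)
        profiles, _ = _window_profiles(config, bundle)
    return profiles[["scaffold", "start", "end", "rho"]].copy()


def apply_coverage_model(
    variants: VariantDataset, config: SimulationConfig, rng: np.random.Generator | None = None
) -> VariantDataset:
    """Introduce missing genotypes and low-depth calls.

    A fraction ``missing_genotype_rate`` of genotype calls becomes ./.
    and an independent fraction ``low_depth_rate`` of DP values is set to
    1 (below the default depth threshold); all other fields are untouched.
    """
    for name, rate in (
        ("missing_genotype_rate", config.missing_genotype_rate),
        ("low_depth_rate", config.low_depth_rate),
    ):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    gt = variants.gt.copy()
    dp = variants.dp.copy()
    if variants.n_variants:
        miss = rng.random(dp.shape) < config.missing_genotype_rate
        gt[miss] = -1
        low = rng.random(dp.shape) < config.low_depth_rate
        dp[low] = 1
    return VariantDataset(
        samples=variants.samples,
        scaffold=variants.scaffold,
        pos=variants.pos,
        ref=variants.ref,
        alt=variants.alt,
        qual=variants.qual,
        mq=variants.mq,
        gt=gt,
        dp=dp,
        multiallelic=variants.multiallelic,
    )


# ---------------------------------------------------------------------------
# Window-level covariate generator (for regression validation at scale)
# ---------------------------------------------------------------------------


def simulate_window_covariates(
    config: SimulationConfig, n_windows: int, seed: int | None = None,
    n_4d_sites: int = 3000, n_syn_sites: int = 3000,
) -> pd.DataFrame:
    """Directly simulate a window table with the configured covariance structure.

    Bypasses the base-level genome: draws per-window rho, gene density, GC
    and mutation multiplier, builds the linked-selection diversity
    multiplier exp(b_rho z(rho) + b_gd z(gd)), and samples pi_4D and
    per-site dS with Poisson counting noise at realistic per-window site
    totals.  Used to validate the regression stage at window counts that a
    desk-scale base-level simulation cannot reach.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rho_mu, rho_sd = config.rho_profile
    rho = np.maximum(rng.normal(rho_mu, rho_sd, n_windows), 0.0)
    gd = np.clip(rng.normal(0.04, 0.015, n_windows), 0.003, 0.25)
    gc = np.clip(rng.normal(0.32, 0.02, n_windows), 0.2, 0.5)
    mult = rng.lognormal(0.0, config.mutation_rate_multiplier_sd, n_windows)
    mult /= mult.mean()

    def zscore(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    b_rho, b_gd = config.linked_selection_coupling
    linked = np.exp(b_rho * zscore(rho) + b_gd * zscore(gd))
    linked /= linked.mean()

    theta = config.populations[0][2]
    n_hap = 2 * config.populations[0][1]
    h = _harmonic(n_hap)
    exp_pi = theta * mult * linked
    # Poisson segregating-site counting noise at the window's 4D site total
    s_counts = rng.poisson(exp_pi * h * n_4d_sites)
    pi_4d = s_counts / (h * n_4d_sites)
    d_counts = rng.poisson(config.divergence_rate_neutral * mult * n_syn_sites)
    ds = d_counts / n_syn_sites
    return pd.DataFrame(
        {
            "pi_4d": pi_4d,
            "gc": gc,
            "rho": rho,
            "gene_density": gd,
            "ds": ds,
            "true_mult": mult,
            "true_linked": linked,
        }
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fasta(scaffolds: dict[str, np.ndarray], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(scaffolds):
            fh.write(f">{name}\n")
            s = decode_seq(scaffolds[name])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(bundle: GenomeBundle, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(bundle.scaffolds):
            fh.write(f"##sequence-region {name} 1 {len(bundle.scaffolds[name])}\n")
        for gene in sorted(bundle.genes, key=lambda g: (g.scaffold, g.span)):
            lo, hi = gene.span
            gid = gene.gene_id
            fh.write(
                f"{gene.scaffold}\tleptidiv_sim\tgene\t{lo + 1}\t{hi}\t.\t"
                f"{gene.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{gene.scaffold}\tleptidiv_sim\tmRNA\t{lo + 1}\t{hi}\t.\t"
                f"{gene.strand}\t.\tID={gid}.t1;Parent={gid}\n"
            )
            segs = sorted(gene.cds_segments)
            order = list(reversed(segs)) if gene.strand == "-" else segs
            phase = gene.phase
            phases = {}
            cum = 0
            for s, e in order:
                phases[(s, e)] = (3 - cum % 3 + phase) % 3 if cum else phase
                cum += e - s
            for s, e in segs:
                fh.write(
                    f"{gene.scaffold}\tleptidiv_sim\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t{phases[(s, e)]}\tID={gid}.cds;Parent={gid}.t1\n"
                )


def write_vcf(ds: VariantDataset, path, contigs: dict[str, int] | None = None) -> None:
    """Write the dataset as a VCFv4.2 text file (GT:DP, INFO/MQ).

    Genotypes are written unphased with alleles in sorted order.
    """
    if ds.n_variants:
        miss = (ds.gt < 0).any(axis=2)
        cnt = np.clip(ds.gt, 0, 1).sum(axis=2)
        idx = np.where(miss, 3, cnt)
        gt_lookup = np.array(["0/0", "0/1", "1/1", "./."])
        dp_str = np.where(ds.dp < 0, ".", ds.dp.astype("U10"))
        sample_str = np.char.add(
            np.char.add(gt_lookup[idx], ":"), dp_str
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=leptidiv_sim\n")
        if contigs:
            for name in sorted(contigs):
                fh.write(f"##contig=<ID={name},length={contigs[name]}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for vi in range(ds.n_variants):
            fh.write(
                f"{ds.scaffold[vi]}\t{ds.pos[vi] + 1}\t.\t{ds.ref[vi]}\t"
                f"{ds.alt[vi]}\t{ds.qual[vi]:.1f}\t.\tMQ={ds.mq[vi]:.2f}\tGT:DP\t"
                + "\t".join(sample_str[vi])
                + "\n"
            )


def write_rho_bed(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_manifest(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for pop, n, _ in config.populations:
            for i in range(n):
                fh.write(f"{pop}_{i + 1:02d}\t{pop}\n")


def simulate_dataset(config: SimulationConfig, outdir) -> dict:
    """Run the full generator and write every output file.

    Writes reference.fasta, genes.gff3, variants.vcf, outgroup.fasta,
    rho.bed, manifest.tsv, truth_windows.tsv and truth_params.json into
    ``outdir`` and returns the in-memory objects for direct use.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_reference(config)
    scmap = build_site_class_map(bundle)
    profiles, _grid = _window_profiles(config, bundle)
    variants, truth = simulate_polymorphisms(config, bundle, scmap, profiles)
    variants = apply_coverage_model(variants, config)
    outgroup, _ = simulate_divergence(config, bundle, scmap, profiles, variants)
    rho = simulate_rho_track(config, profiles)

    write_fasta(bundle.scaffolds, outdir / "reference.fasta")
    write_gff3(bundle, outdir / "genes.gff3")
    write_vcf(variants, outdir / "variants.vcf", bundle.scaffold_lengths())
    write_fasta(outgroup, outdir / "outgroup.fasta")
    write_rho_bed(rho, outdir / "rho.bed")
    write_manifest(config, outdir / "manifest.tsv")
    truth.windows.to_csv(outdir / "truth_windows.tsv", sep="\t", index=False,
                         float_format="%.10g")
    with open(outdir / "truth_params.json", "w") as fh:
        json.dump(truth.params, fh, indent=2, sort_keys=True)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True, default=str)
    return {
        "bundle": bundle,
        "scmap": scmap,
        "profiles": profiles,
        "variants": variants,
        "outgroup": outgroup,
        "rho": rho,
        "truth": truth,
    }
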