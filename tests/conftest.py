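"""Shared fixtures: tiny hand-built genomes and a small simulated dataset."""

import numpy as np
import pytest

import leptidiv as L
from leptidiv.annotation_sites import encode_seq


def make_bundle(seqs: dict[str, str], genes=None) -> L.GenomeBundle:
    return L.GenomeBundle(
        scaffolds={k: encode_seq(v) for k, v in seqs.items()},
        genes=genes or [],
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end simulated dataset analysed in memory.

    Clean coverage (no missing/low-depth genotypes) so estimates can be
    compared against the configured truth directly.
    """
    from leptidiv.annotation_sites import build_site_class_map
    from leptidiv.synthetic_data import _window_profiles
    from leptidiv.selection_stats import classify_polymorphisms, call_substitutions
    from leptidiv.variant_filters import apply_filters, allele_counts

    cfg = L.SimulationConfig(
        seed=97,
        n_scaffolds=3,
        scaffold_length=200_000,
        n_genes_per_scaffold=8,
        window_size=50_000,
        missing_genotype_rate=0.0,
        low_depth_rate=0.0,
    )
    bundle = L.generate_reference(cfg)
    scmap = build_site_class_map(bundle)
    profiles, _ = _window_profiles(cfg, bundle)
    ds, truth = L.simulate_polymorphisms(cfg, bundle, scmap, profiles)
    outgroup, _ = L.simulate_divergence(cfg, bundle, scmap, profiles)
    manifest = {s: s.rsplit("_", 1)[0] for s in ds.samples}
    pv = apply_filters(ds, manifest, bundle.scaffold_lengths(), n_mask=scmap.n_mask)
    pv = allele_counts(pv, outgroup)
    pv = classify_polymorphisms(pv, scmap)
    subs = call_substitutions(pv, scmap, bundle.scaffolds, outgroup)
    grid = L.WindowGrid(cfg.window_size, bundle.scaffold_lengths())
    return {
        "config": cfg,
        "bundle": bundle,
        "scmap": scmap,
        "profiles": profiles,
        "variants": ds,
        "outgroup": outgroup,
        "pv": pv,
        "subs": subs,
        "grid": grid,
        "truth": truth,
    }


def analyse(cfg: L.SimulationConfig):
    """Run simulator + filters + classification in memory for one config."""
    from leptidiv.annotation_sites import build_site_class_map
    from leptidiv.synthetic_data import _window_profiles
    from leptidiv.selection_stats import classify_polymorphisms, call_substitutions
    from leptidiv.variant_filters import apply_filters, allele_counts

    bundle = L.generate_reference(cfg)
    scmap = build_site_class_map(bundle)
    profiles, _ = _window_profiles(cfg, bundle)
    ds, truth = L.simulate_polymorphisms(cfg, bundle, scmap, profiles)
    ds = L.apply_coverage_model(ds, cfg)
    outgroup, _ = L.simulate_divergence(cfg, bundle, scmap, profiles)
    manifest = {s: s.rsplit("_", 1)[0] for s in ds.samples}
    pv = apply_filters(ds, manifest, bundle.scaffold_lengths(), n_mask=scmap.n_mask)
    pv = allele_counts(pv, outgroup)
    pv = classify_polymorphisms(pv, scmap)
    subs = call_substitutions(pv, scmap, bundle.scaffolds, outgroup)
    return {
        "bundle": bundle,
        "scmap": scmap,
        "profiles": profiles,
        "pv": pv,
        "subs": subs,
        "truth": truth,
        "grid": L.WindowGrid(cfg.window_size, bundle.scaffold_lengths()),
    }
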