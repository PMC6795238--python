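"""NG86 site counting, variant/substitution classification, MK alpha."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import leptidiv as L
from leptidiv.annotation_sites import GeneModel, encode_seq
from leptidiv.selection_stats import (
    alpha_from_counts,
    classify_change,
    estimate_alpha,
    jc69,
)
from conftest import make_bundle

BASES = "ACGT"
SENSE_CODONS = [
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def ng86_enumeration(codon: str) -> tuple[float, float]:
    """Independent NG86 oracle: enumerate all 9 single-nucleotide mutations."""
    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut_aa = str(Seq(codon[:pos] + b + codon[pos + 1:]).translate())
            if mut_aa == aa and mut_aa != "*":
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


class TestNG86:
    def test_examples(self):
        assert L.count_sites_ng86("GGG") == pytest.approx((2.0, 1.0))
        assert L.count_sites_ng86("TGG") == pytest.approx((3.0, 0.0))

    def test_matches_enumeration_for_all_61_sense_codons(self):
        assert len(SENSE_CODONS) == 61
        for codon in SENSE_CODONS:
            n, s = L.count_sites_ng86(codon)
            n_ref, s_ref = ng86_enumeration(codon)
            assert (n, s) == pytest.approx((n_ref, s_ref))
            assert n + s == pytest.approx(3.0)  # conservation

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            L.count_sites_ng86("TAA")


class TestClassifyChange:
    def _idx(self, codon):
        c = encode_seq(codon)
        return int(c[0]) * 16 + int(c[1]) * 4 + int(c[2])

    def test_synonymous(self):
        # GGA -> GGT: Gly -> Gly
        assert classify_change(self._idx("GGA"), 2, encode_seq("T")[0]) == "synonymous"

    def test_nonsynonymous(self):
        # GGA -> GAA: Gly -> Glu
        assert (
            classify_change(self._idx("GGA"), 1, encode_seq("A")[0]) == "nonsynonymous"
        )

    def test_stop_involving(self):
        # CAA -> TAA creates a stop
        assert (
            classify_change(self._idx("CAA"), 0, encode_seq("T")[0]) == "stop_involving"
        )

    def test_classification_completeness(self, small_sim):
        """Every retained coding SNP falls in exactly one class and the
        tallies reconcile with the input count."""
        pv = small_sim["pv"]
        scmap = small_sim["scmap"]
        for pop in pv.populations():
            df = pv.snps[pop]
            coding = np.array(
                [
                    scmap.codon_id[s][p] >= 0
                    for s, p in zip(df["scaffold"], df["pos"])
                ]
            )
            labels = df.loc[coding, "coding_class"]
            assert set(labels) <= {
                "synonymous",
                "nonsynonymous",
                "stop_involving",
                "excluded_n",
            }
            assert (df.loc[~coding, "coding_class"] == "").all()
            assert len(labels) + (~coding).sum() == len(df)


class TestSubstitutionCalls:
    # one forward gene ATG GGA GGA: position 5 is the third base of a GGA
    # codon, a four-fold degenerate site

    def test_fixed_difference_called(self):
        seq = "ATGGGAGGA" + "ACGT" * 4
        bundle = make_bundle({"s": seq}, [GeneModel("g", "s", "+", [(0, 9)])])
        scmap = L.build_site_class_map(bundle)
        out = bundle.scaffolds["s"].copy()
        out[5] = encode_seq("T")[0]  # GGA -> GGT at 4D site: synonymous
        pv = L.PopulationVariants(
            snps={"P": pd.DataFrame(columns=["scaffold", "pos", "ref", "alt", "alt_count", "n_hap"])},
            callable_mask={"P": {"s": np.ones(len(seq), bool)}},
        )
        subs = L.call_substitutions(pv, scmap, bundle.scaffolds, {"s": out})
        assert len(subs["P"]) == 1
        row = subs["P"].iloc[0]
        assert row["pos"] == 5
        assert row["classification"] == "synonymous"
        assert bool(row["fourfold"])

    def test_polymorphic_site_never_substitution(self):
        seq = "ATGGGAGGA" + "ACGT" * 4
        bundle = make_bundle({"s": seq}, [GeneModel("g", "s", "+", [(0, 9)])])
        scmap = L.build_site_class_map(bundle)
        out = bundle.scaffolds["s"].copy()
        out[5] = encode_seq("T")[0]
        snp = pd.DataFrame(
            {
                "scaffold": ["s"],
                "pos": [5],
                "ref": ["A"],
                "alt": ["G"],
                "alt_count": [1],
                "n_hap": [4],
            }
        )
        pv = L.PopulationVariants(
            snps={"P": snp},
            callable_mask={"P": {"s": np.ones(len(seq), bool)}},
        )
        subs = L.call_substitutions(pv, scmap, bundle.scaffolds, {"s": out})
        assert len(subs["P"]) == 0

    def test_identical_outgroup_no_substitution(self):
        seq = "ATGGGAGGA" + "ACGT" * 4
        bundle = make_bundle({"s": seq}, [GeneModel("g", "s", "+", [(0, 9)])])
        scmap = L.build_site_class_map(bundle)
        pv = L.PopulationVariants(
            snps={"P": pd.DataFrame(columns=["scaffold", "pos", "ref", "alt", "alt_count", "n_hap"])},
            callable_mask={"P": {"s": np.ones(len(seq), bool)}},
        )
        subs = L.call_substitutions(pv, scmap, bundle.scaffolds, dict(bundle.scaffolds))
        assert len(subs["P"]) == 0

    def test_outgroup_n_excluded(self):
        seq = "ATGGGAGGA" + "ACGT" * 4
        bundle = make_bundle({"s": seq}, [GeneModel("g", "s", "+", [(0, 9)])])
        scmap = L.build_site_class_map(bundle)
        out = bundle.scaffolds["s"].copy()
        out[5] = 4  # N in the outgroup
        pv = L.PopulationVariants(
            snps={"P": pd.DataFrame(columns=["scaffold", "pos", "ref", "alt", "alt_count", "n_hap"])},
            callable_mask={"P": {"s": np.ones(len(seq), bool)}},
        )
        subs = L.call_substitutions(pv, scmap, bundle.scaffolds, {"s": out})
        assert len(subs["P"]) == 0

    def test_total_count_invariant_under_outgroup_swap(self, small_sim):
        """Swapping reference and outgroup leaves total fixed-difference
        counts unchanged (lineage assignment is not counted here)."""
        pv = small_sim["pv"]
        scmap = small_sim["scmap"]
        bundle = small_sim["bundle"]
        out = small_sim["outgroup"]
        fwd = L.call_substitutions(pv, scmap, bundle.scaffolds, out)
        # swap: outgroup plays reference; candidate set is symmetric since
        # the fixed population allele equals reference at non-variant sites
        pv_clean = L.PopulationVariants(
            snps={
                "LsSwe": pv.snps["LsSwe"][["scaffold", "pos", "ref", "alt", "alt_count", "n_hap"]]
            },
            callable_mask={"LsSwe": pv.callable_mask["LsSwe"]},
        )
        pv_clean.snps["LsSwe"].attrs["fixed_alt"] = None
        rev_ref = {s: out[s] for s in out}
        rev_out = {s: bundle.scaffolds[s] for s in bundle.scaffolds}
        # drop SNPs whose position has a swap-side difference to keep the
        # comparison on monomorphic sites only
        fwd_clean = L.call_substitutions(pv_clean, scmap, bundle.scaffolds, out)
        rev = L.call_substitutions(pv_clean, scmap, rev_ref, rev_out)
        assert len(fwd_clean["LsSwe"]) == len(rev["LsSwe"])
        assert len(fwd["LsSwe"]) > 0


class TestWindowRatios:
    def test_ratio_arithmetic(self, small_sim):
        wsel = L.window_selection_stats(
            small_sim["pv"], small_sim["subs"], small_sim["scmap"], small_sim["grid"]
        )
        ok = wsel.dropna(subset=["pn_ps"])
        expect = (ok["pn"] / ok["ln"]) / (ok["ps"] / ok["ls"])
        assert np.allclose(ok["pn_ps"], expect)
        # zero synonymous polymorphisms -> missing, never infinite
        zero_ps = wsel[(wsel["ps"] == 0)]
        assert zero_ps["pn_ps"].isna().all()
        assert np.isfinite(wsel["pn_ps"].dropna()).all()

    def test_ln_ls_conservation(self, small_sim):
        """LN + LS equals 3 x number of fully callable analyzed codons."""
        scmap = small_sim["scmap"]
        pv = small_sim["pv"]
        wsel = L.window_selection_stats(pv, small_sim["subs"], scmap, small_sim["grid"])
        for pop, sub in wsel.groupby("population"):
            total = sub["ln"].sum() + sub["ls"].sum()
            mask = pv.callable_mask[pop]
            n_codons = 0
            for si, scaf in enumerate(scmap.scaffold_names):
                sel = (scmap.codon_scaffold == si) & scmap.codon_valid & (scmap.codons >= 0)
                sites = scmap.codon_sites[sel]
                n_codons += int(mask[scaf][sites].all(axis=1).sum())
            assert total == pytest.approx(3.0 * n_codons)

    def test_jc69_on_small_p_is_near_identity(self):
        p = np.array([0.0, 0.01, 0.05])
        d = jc69(p)
        assert d[0] == 0
        assert d[1] == pytest.approx(0.01, rel=0.02)
        assert np.isnan(jc69(np.array([0.8]))[0])


class TestAlpha:
    def test_point_estimate_examples(self):
        assert alpha_from_counts(1, 1, 2, 1) == pytest.approx(0.5)
        # pN/pS == dN/dS -> neutral expectation alpha = 0
        assert alpha_from_counts(3, 6, 5, 10) == pytest.approx(0.0)
        assert np.isnan(alpha_from_counts(1, 0, 2, 1))
        assert np.isnan(alpha_from_counts(1, 5, 0, 1))

    def test_bootstrap_reproducible_and_brackets_point(self):
        rng = np.random.default_rng(0)
        events = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(40)],
                "pn": rng.poisson(2, 40),
                "ps": rng.poisson(4, 40),
                "dn": rng.poisson(8, 40),
                "ds": rng.poisson(10, 40),
            }
        )
        r1 = estimate_alpha(events, bootstrap_reps=100, seed=5)
        r2 = estimate_alpha(events, bootstrap_reps=100, seed=5)
        assert r1["alpha"] == r2["alpha"]
        assert r1["ci_low"] == r2["ci_low"] and r1["se"] == r2["se"]
        assert r1["ci_low"] <= r1["alpha"] <= r1["ci_high"]
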