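"""Site classification, degeneracy tables and window covariates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import leptidiv as L
from leptidiv.annotation_sites import (
    CODING_CLASSES,
    DEGENERACY,
    FOURFOLD_CODON,
    GENIC_NC,
    INTERGENIC,
    INTRON,
    MASKED,
    NG86_SYN_SITES,
    POS1,
    POS2,
    POS3,
    STOP_CODON,
    GeneModel,
    WindowGrid,
    encode_seq,
    gc_content,
    window_gc,
)
from conftest import make_bundle

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


class TestCodonDegeneracy:
    def test_examples(self):
        assert L.classify_codon_degeneracy("GGA", 2) == 4  # glycine GGN family
        for pos in range(3):
            assert L.classify_codon_degeneracy("ATG", pos) == 1  # unique Met codon

    def test_ambiguous_codon_is_masked_not_error(self):
        assert L.classify_codon_degeneracy("GGN", 2) == "masked"
        assert L.classify_codon_degeneracy("TAA", 0) == "masked"  # stop

    def test_degeneracy_matches_translation_oracle(self):
        """Exhaustive check of the degeneracy table against Bio translation."""
        for codon in ALL_CODONS:
            aa = str(Seq(codon).translate())
            if aa == "*":
                continue
            for pos in range(3):
                expected = sum(
                    str(Seq(codon[:pos] + b + codon[pos + 1:]).translate()) == aa
                    for b in BASES
                )
                assert L.classify_codon_degeneracy(codon, pos) == expected

    def test_32_codons_are_fourfold_at_third_position(self):
        n_4d = sum(
            1
            for codon in ALL_CODONS
            if str(Seq(codon).translate()) != "*"
            and L.classify_codon_degeneracy(codon, 2) == 4
        )
        assert n_4d == 32
        assert int(FOURFOLD_CODON.sum()) == 32


class TestSiteClassMap:
    def test_forward_gene_codon_positions(self):
        seq = "TT" + "ATGGCTGCT" + "TTTT"  # gene at [2, 11)
        bundle = make_bundle(
            {"s": seq},
            [GeneModel("g1", "s", "+", [(2, 11)])],
        )
        scmap = L.build_site_class_map(bundle)
        assert list(scmap.classes["s"][2:11]) == [1, 2, 3] * 3
        assert list(scmap.classes["s"][:2]) == [INTERGENIC] * 2

    def test_reverse_gene_labels_mirrored(self):
        # genome segment is the reverse complement of transcript ATGGCTGCT,
        # so the transcriptionally first codon starts at the highest coordinate
        seq = "TT" + "AGCAGCCAT" + "TTTT"
        bundle = make_bundle(
            {"s": seq},
            [GeneModel("g1", "s", "-", [(2, 11)])],
        )
        scmap = L.build_site_class_map(bundle)
        assert list(scmap.classes["s"][2:11]) == [3, 2, 1] * 3

    def test_no_genes_all_intergenic_except_n(self):
        bundle = make_bundle({"s": "ACGTNNACGT"})
        scmap = L.build_site_class_map(bundle)
        cls = scmap.classes["s"]
        assert (cls[[0, 1, 2, 3, 6, 7, 8, 9]] == INTERGENIC).all()
        assert (cls[[4, 5]] == MASKED).all()

    def test_partition_and_codon_balance(self, small_sim):
        scmap = small_sim["scmap"]
        bundle = small_sim["bundle"]
        for scaf in scmap.scaffold_names:
            counts = np.bincount(scmap.classes[scaf], minlength=7)
            assert counts.sum() == len(bundle.scaffolds[scaf])
        p = [
            sum((scmap.classes[s] == c).sum() for s in scmap.scaffold_names)
            for c in (POS1, POS2, POS3)
        ]
        assert p[0] == p[1] == p[2]

    def test_fourfold_only_at_position3(self, small_sim):
        scmap = small_sim["scmap"]
        for scaf in scmap.scaffold_names:
            ff = scmap.fourfold[scaf]
            assert (scmap.classes[scaf][ff] == POS3).all()

    def test_strand_symmetry(self):
        """Reverse-complementing the scaffold and flipping strands preserves
        the multiset of site classes."""
        cfg = L.SimulationConfig(
            seed=5, n_scaffolds=1, scaffold_length=30_000, n_genes_per_scaffold=3
        )
        bundle = L.generate_reference(cfg)
        scmap = L.build_site_class_map(bundle)
        (scaf,) = bundle.scaffolds
        length = len(bundle.scaffolds[scaf])
        rc = make_bundle({scaf: ""})
        rc.scaffolds[scaf] = np.ascontiguousarray(
            (3 - bundle.scaffolds[scaf])[::-1]
        )
        flipped = [
            GeneModel(
                g.gene_id,
                g.scaffold,
                "-" if g.strand == "+" else "+",
                sorted((length - e, length - s) for s, e in g.cds_segments),
                g.phase,
            )
            for g in bundle.genes
        ]
        rc.genes = flipped
        scmap_rc = L.build_site_class_map(rc)
        orig = np.bincount(scmap.classes[scaf], minlength=7)
        mirror = np.bincount(scmap_rc.classes[scaf], minlength=7)
        assert (orig == mirror).all()

    def test_bad_cds_length_skipped_with_warning(self):
        bundle = make_bundle(
            {"s": "ATGGCTGC" + "T" * 20},
            [GeneModel("g1", "s", "+", [(0, 8)])],  # 8 bp: not a codon multiple
        )
        with pytest.warns(UserWarning, match="not a multiple of 3"):
            scmap = L.build_site_class_map(bundle)
        assert scmap.qc["genes_skipped_bad_length"] == 1
        assert not np.isin(scmap.classes["s"], CODING_CLASSES).any()

    def test_overlapping_genes_masked(self):
        seq = "ATGGCTGCTGCTTTT" + "T" * 10
        genes = [
            GeneModel("a", "s", "+", [(0, 9)]),
            GeneModel("b", "s", "+", [(6, 15)]),
        ]
        scmap = L.build_site_class_map(make_bundle({"s": seq}, genes))
        assert (scmap.classes["s"][6:9] == MASKED).all()
        assert scmap.qc["sites_overlap_masked"] == 3


class TestWindowCovariates:
    def test_gene_density_arithmetic(self):
        # 5,000 coding in a 100,000 window with no Ns -> 0.05
        cfg_cls = np.full(100_000, INTERGENIC, dtype=np.int8)
        cfg_cls[:5000] = POS1
        scmap = L.SiteClassMap(
            classes={"s": cfg_cls},
            fourfold={"s": np.zeros(100_000, bool)},
            n_mask={"s": np.zeros(100_000, bool)},
            codon_id={"s": np.full(100_000, -1, np.int64)},
            codon_offset={"s": np.full(100_000, -1, np.int8)},
            scaffold_names=["s"],
        )
        grid = WindowGrid(100_000, {"s": 100_000})
        assert L.gene_density(scmap, grid)["gene_density"][0] == pytest.approx(0.05)

    def test_gene_density_excludes_n_from_denominator(self):
        cls = np.full(100_000, INTERGENIC, dtype=np.int8)
        nn = np.zeros(100_000, bool)
        cls[:5000] = POS2
        cls[50_000:] = MASKED
        nn[50_000:] = True
        scmap = L.SiteClassMap(
            classes={"s": cls},
            fourfold={"s": np.zeros(100_000, bool)},
            n_mask={"s": nn},
            codon_id={"s": np.full(100_000, -1, np.int64)},
            codon_offset={"s": np.full(100_000, -1, np.int8)},
            scaffold_names=["s"],
        )
        grid = WindowGrid(100_000, {"s": 100_000})
        assert L.gene_density(scmap, grid)["gene_density"][0] == pytest.approx(0.10)

    def test_all_n_window_is_missing(self):
        cls = np.full(1000, MASKED, dtype=np.int8)
        scmap = L.SiteClassMap(
            classes={"s": cls},
            fourfold={"s": np.zeros(1000, bool)},
            n_mask={"s": np.ones(1000, bool)},
            codon_id={"s": np.full(1000, -1, np.int64)},
            codon_offset={"s": np.full(1000, -1, np.int8)},
            scaffold_names=["s"],
        )
        grid = WindowGrid(1000, {"s": 1000})
        assert np.isnan(L.gene_density(scmap, grid)["gene_density"][0])

    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5)],
    )
    def test_gc_content(self, seq, expected):
        assert gc_content(encode_seq(seq)) == pytest.approx(expected)

    def test_gc_empty_selection_missing(self):
        assert np.isnan(gc_content(encode_seq("NNN")))

    def test_window_rho_weighted_mean(self):
        grid = WindowGrid(100_000, {"s": 100_000})
        track = pd.DataFrame(
            {
                "scaffold": ["s", "s"],
                "start": [0, 60_000],
                "end": [60_000, 100_000],
                "rho": [0.01, 0.02],
            }
        )
        res = L.window_rho(track, grid)
        assert res["rho"][0] == pytest.approx(0.014)

    def test_window_rho_full_and_missing(self):
        grid = WindowGrid(1000, {"s": 2000})
        track = pd.DataFrame(
            {"scaffold": ["s"], "start": [0], "end": [1000], "rho": [0.02]}
        )
        res = L.window_rho(track, grid)
        assert res["rho"][0] == pytest.approx(0.02)
        assert np.isnan(res["rho"][1])  # no data -> missing

    def test_negative_rho_rejected(self):
        grid = WindowGrid(1000, {"s": 1000})
        track = pd.DataFrame(
            {"scaffold": ["s"], "start": [0], "end": [1000], "rho": [-0.1]}
        )
        with pytest.raises(ValueError, match="negative"):
            L.window_rho(track, grid)

    def test_window_grid_halving_doubles_windows(self):
        lengths = {"a": 200_000, "b": 150_000}
        n100 = sum(WindowGrid(100_000, lengths).n_windows(s) for s in lengths)
        n50 = sum(WindowGrid(50_000, lengths).n_windows(s) for s in lengths)
        assert n100 == 4 and n50 == 7  # doubling +/- one terminal per scaffold
        assert abs(n50 - 2 * n100) <= len(lengths)


class TestRoundTrip:
    def test_gff_fasta_round_trip(self, small_sim, tmp_path):
        from leptidiv.annotation_sites import read_genome_bundle
        from leptidiv.synthetic_data import write_fasta, write_gff3

        bundle = small_sim["bundle"]
        write_fasta(bundle.scaffolds, tmp_path / "r.fasta")
        write_gff3(bundle, tmp_path / "g.gff3")
        back = read_genome_bundle(tmp_path / "r.fasta", tmp_path / "g.gff3")
        assert sorted(back.scaffolds) == sorted(bundle.scaffolds)
        for s in bundle.scaffolds:
            assert (back.scaffolds[s] == bundle.scaffolds[s]).all()
        orig = {g.gene_id: g for g in bundle.genes}
        assert len(back.genes) == len(orig)
        for g in back.genes:
            ref = orig[g.gene_id]
            assert g.strand == ref.strand
            assert g.cds_segments == ref.cds_segments
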