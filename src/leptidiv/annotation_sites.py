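"""Per-site functional classification and per-window annotation covariates.

Builds, from a reference genome (FASTA) plus gene models (GFF3 CDS features),
a per-site map of functional classes -- codon positions 1/2/3 (with a
four-fold-degeneracy flag on third positions), intron, genic noncoding
(exonic non-CDS, e.g. UTRs), intergenic, and masked -- and computes the
window-level covariates used downstream: gene density, GC content and the
length-weighted window average of a population recombination-rate (rho)
track.

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based closed convention is converted at the reader boundary.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger("leptidiv")

# ---------------------------------------------------------------------------
# Sequence encoding: A,C,G,T -> 0..3; anything else (N, gaps) -> 4.
# Complement of a base code b < 4 is 3 - b.
# ---------------------------------------------------------------------------

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the code alphabet; N stays N."""
    out = np.where(codes < 4, 3 - codes, codes)
    return out[::-1]


# ---------------------------------------------------------------------------
# Codon tables (standard genetic code unless another NCBI table id is given).
# Codon index = 16*b1 + 4*b2 + b3 over base codes.
# ---------------------------------------------------------------------------


def _codon_tables(table_id: int = 1):
    table = unambiguous_dna_by_id[table_id]
    aa = np.empty(64, dtype="U1")
    for i, (b1, b2, b3) in enumerate(itertools.product(BASES, BASES, BASES)):
        codon = b1 + b2 + b3
        aa[i] = table.forward_table.get(codon, "*")
    deg = np.zeros((64, 3), dtype=np.int8)
    for idx in range(64):
        if aa[idx] == "*":
            continue
        for pos in range(3):
            n_same = 0
            for b in range(4):
                mut = idx + (b - (idx >> (2 * (2 - pos)) & 3)) * 4 ** (2 - pos)
                if aa[mut] == aa[idx]:
                    n_same += 1
            deg[idx, pos] = n_same
    # NG86 fractional site counts: per position, (# of the 3 possible single
    # mutations that are synonymous)/3 synonymous sites; mutations to stop
    # codons count as nonsynonymous.  Totals sum to 3 per sense codon.
    syn_sites = np.full(64, np.nan)
    for idx in range(64):
        if aa[idx] == "*":
            continue
        s = 0.0
        for pos in range(3):
            cur = idx >> (2 * (2 - pos)) & 3
            for b in range(4):
                if b == cur:
                    continue
                mut = idx + (b - cur) * 4 ** (2 - pos)
                if aa[mut] == aa[idx]:
                    s += 1.0 / 3.0
        syn_sites[idx] = s
    return aa, deg, syn_sites


CODON_AA, DEGENERACY, NG86_SYN_SITES = _codon_tables(1)
with np.errstate(invalid="ignore"):
    NG86_NONSYN_SITES = 3.0 - NG86_SYN_SITES
FOURFOLD_CODON = DEGENERACY[:, 2] == 4
STOP_CODON = CODON_AA == "*"


def codon_index(codes3: np.ndarray) -> np.ndarray:
    """Codon index 0..63 from an (..., 3) array of base codes; -1 if any N."""
    codes3 = np.asarray(codes3)
    idx = codes3[..., 0] * 16 + codes3[..., 1] * 4 + codes3[..., 2]
    return np.where((codes3 < 4).all(axis=-1), idx, -1)


def classify_codon_degeneracy(codon: str, position: int, table_id: int = 1):
    """Degeneracy (1..4) of `position` (0-based) in `codon`.

    Returns the number of nucleotides at that position that preserve the
    encoded amino acid.  A codon containing an ambiguous base returns the
    string ``"masked"`` (the site is excluded, not an error); stop codons
    also return ``"masked"`` as they carry no degeneracy semantics.
    """
    if position not in (0, 1, 2):
        raise ValueError(f"codon position must be 0, 1 or 2, got {position}")
    codes = encode_seq(codon)
    if codes.shape[0] != 3:
        raise ValueError(f"expected a 3-mer, got {codon!r}")
    if (codes >= 4).any():
        return "masked"
    if table_id == 1:
        aa, deg = CODON_AA, DEGENERACY
    else:
        aa, deg, _ = _codon_tables(table_id)
    idx = int(codes[0]) * 16 + int(codes[1]) * 4 + int(codes[2])
    if aa[idx] == "*":
        return "masked"
    return int(deg[idx, position])


# ---------------------------------------------------------------------------
# Site-class codes
# ---------------------------------------------------------------------------

INTERGENIC, POS1, POS2, POS3, INTRON, GENIC_NC, MASKED = range(7)
CLASS_NAMES = {
    INTERGENIC: "intergenic",
    POS1: "codon_pos1",
    POS2: "codon_pos2",
    POS3: "codon_pos3",
    INTRON: "intron",
    GENIC_NC: "genic_noncoding",
    MASKED: "masked",
}
CODING_CLASSES = (POS1, POS2, POS3)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One protein-coding gene: ordered CDS segments in reference coordinates.

    ``cds_segments`` are 0-based half-open (start, end) tuples sorted by
    genomic start; transcription order is derived from ``strand``.  ``phase``
    is the phase of the transcriptionally first segment (bases to skip before
    the first complete codon).  ``exon_segments`` (optional) allow exonic
    non-CDS sequence (UTRs) to be classed as genic noncoding.
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_segments: list[tuple[int, int]]
    phase: int = 0
    exon_segments: list[tuple[int, int]] | None = None

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]


@dataclass
class GenomeBundle:
    """Reference scaffolds (encoded base codes) plus gene models."""

    scaffolds: dict[str, np.ndarray]
    genes: list[GeneModel]

    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}


@dataclass
class WindowGrid:
    """Non-overlapping windows tiled from position 0 of each scaffold.

    The terminal window of a scaffold may be shorter than ``window_size``;
    it is retained in the grid and flagged via ``is_terminal_short``.
    """

    window_size: int
    scaffold_lengths: dict[str, int]

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window size must be positive")

    def n_windows(self, scaffold: str) -> int:
        length = self.scaffold_lengths[scaffold]
        return max(1, -(-length // self.window_size))

    def windows(self, scaffold: str) -> list[tuple[int, int]]:
        length = self.scaffold_lengths[scaffold]
        return [
            (s, min(s + self.window_size, length))
            for s in range(0, max(length, 1), self.window_size)
        ]

    def window_index(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions) // self.window_size

    def table(self) -> pd.DataFrame:
        rows = []
        for scaf in self.scaffold_lengths:
            for start, end in self.windows(scaf):
                rows.append(
                    (scaf, start, end, end - start < self.window_size)
                )
        return pd.DataFrame(
            rows, columns=["scaffold", "start", "end", "is_terminal_short"]
        )


@dataclass
class SiteClassMap:
    """Per-site functional classes plus the codon-level lookup tables.

    ``classes`` holds one int8 code per site (see CLASS_NAMES); ``fourfold``
    flags third codon positions whose codon is four-fold degenerate;
    ``n_mask`` records assembly gaps (N) separately from analysis masking.
    Codon-level arrays map every complete, unambiguous codon to its genomic
    sites (in transcription order), its codon index, gene and strand, so
    variant consequences can be resolved without re-walking the annotation.
    """

    classes: dict[str, np.ndarray]
    fourfold: dict[str, np.ndarray]
    n_mask: dict[str, np.ndarray]
    codon_id: dict[str, np.ndarray]
    codon_offset: dict[str, np.ndarray]
    codons: np.ndarray = field(default_factory=lambda: np.empty(0, np.int16))
    codon_gene: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    codon_strand: np.ndarray = field(default_factory=lambda: np.empty(0, "U1"))
    codon_scaffold: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    codon_sites: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.int64))
    codon_valid: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    scaffold_names: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    qc: dict = field(default_factory=dict)

    def class_counts(self, scaffold: str) -> dict[str, int]:
        counts = np.bincount(self.classes[scaffold], minlength=7)
        return {CLASS_NAMES[i]: int(counts[i]) for i in range(7)}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, np.ndarray]:
    """Read a FASTA file into encoded scaffold arrays (uppercased)."""
    return {
        rec.id: encode_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 CDS (and exon) features.

    CDS segments are grouped by their Parent attribute (or ID when no Parent
    is present); with several transcripts per gene the longest CDS isoform is
    kept.  GFF3 1-based closed coordinates become 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    def parent_of(feat):
        parents = feat.attributes.get("Parent")
        return parents[0] if parents else feat.id

    cds_by_tx: dict[str, list] = {}
    exons_by_tx: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        cds_by_tx.setdefault(parent_of(feat), []).append(feat)
    for feat in db.features_of_type("exon"):
        exons_by_tx.setdefault(parent_of(feat), []).append(feat)

    # map transcript -> gene so isoforms can be collapsed
    gene_of_tx = {}
    for tx_id in cds_by_tx:
        try:
            tx = db[tx_id]
            gene_of_tx[tx_id] = parent_of(tx)
        except gffutils.FeatureNotFoundError:
            gene_of_tx[tx_id] = tx_id

    by_gene: dict[str, list[str]] = {}
    for tx_id, gene_id in gene_of_tx.items():
        by_gene.setdefault(gene_id, []).append(tx_id)

    genes = []
    for gene_id in sorted(by_gene):
        tx_ids = by_gene[gene_id]
        tx_id = max(
            tx_ids, key=lambda t: (sum(f.end - f.start + 1 for f in cds_by_tx[t]), t)
        )
        feats = sorted(cds_by_tx[tx_id], key=lambda f: f.start)
        strand = feats[0].strand
        segments = [(f.start - 1, f.end) for f in feats]
        first = feats[-1] if strand == "-" else feats[0]
        try:
            phase = int(first.frame)
        except (TypeError, ValueError):
            phase = 0
        exon_segments = None
        if tx_id in exons_by_tx:
            exon_segments = sorted(
                (f.start - 1, f.end) for f in exons_by_tx[tx_id]
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=feats[0].seqid,
                strand=strand,
                cds_segments=segments,
                phase=phase,
                exon_segments=exon_segments,
            )
        )
    return genes


def read_genome_bundle(fasta_path, gff_path) -> GenomeBundle:
    return GenomeBundle(scaffolds=read_fasta(fasta_path), genes=read_gff3(gff_path))


def read_rho_track(path) -> pd.DataFrame:
    """Read a BED-like rho track: scaffold, start, end, rho (0-based half-open)."""
    track = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["scaffold", "start", "end", "rho"],
        comment="#",
    )
    if (track["rho"] < 0).any():
        raise ValueError("rho track contains negative values")
    return track


# ---------------------------------------------------------------------------
# Site-class map construction
# ---------------------------------------------------------------------------


def _transcription_positions(gene: GeneModel) -> np.ndarray:
    """Genomic positions of the CDS in transcription (5'->3') order."""
    segs = sorted(gene.cds_segments)
    if gene.strand == "-":
        parts = [np.arange(e - 1, s - 1, -1) for s, e in reversed(segs)]
    else:
        parts = [np.arange(s, e) for s, e in segs]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def build_site_class_map(bundle: GenomeBundle) -> SiteClassMap:
    """Label every site of every scaffold with its functional class.

    CDS sites get strand-aware codon positions (reverse-complemented codons
    on the minus strand, so the transcriptionally first codon of a minus
    gene starts at its highest coordinate).  Non-CDS sites inside a gene
    span become intron (or genic noncoding when exon features say so); all
    remaining non-N sites are intergenic; N runs are masked.

    Genes whose CDS length is not a multiple of three after phase trimming
    are skipped with a warning and counted in the QC report.  Where two
    genes claim the same site with conflicting codon structure the site is
    masked for coding analyses and both codons are invalidated.
    """
    scaffold_names = sorted(bundle.scaffolds)
    scaf_index = {name: i for i, name in enumerate(scaffold_names)}
    classes = {}
    n_mask = {}
    codon_id = {}
    codon_offset = {}
    for name in scaffold_names:
        seq = bundle.scaffolds[name]
        cls = np.full(len(seq), INTERGENIC, dtype=np.int8)
        nn = seq >= 4
        cls[nn] = MASKED
        classes[name] = cls
        n_mask[name] = nn
        codon_id[name] = np.full(len(seq), -1, dtype=np.int64)
        codon_offset[name] = np.full(len(seq), -1, dtype=np.int8)

    qc = {
        "genes_total": len(bundle.genes),
        "genes_skipped_bad_length": 0,
        "codons_internal_stop": 0,
        "codons_with_n": 0,
        "sites_overlap_masked": 0,
        "phase_trimmed_sites": 0,
    }

    codons_list = []
    codon_gene_list = []
    codon_strand_list = []
    codon_scaf_list = []
    codon_sites_list = []
    codon_valid_list = []
    gene_ids = []

    genes = sorted(bundle.genes, key=lambda g: (g.scaffold, g.span, g.gene_id))
    for gene in genes:
        if gene.scaffold not in bundle.scaffolds:
            raise ValueError(f"gene {gene.gene_id} on unknown scaffold {gene.scaffold}")
        seq = bundle.scaffolds[gene.scaffold]
        lo, hi = gene.span
        if lo < 0 or hi > len(seq):
            raise ValueError(f"gene {gene.gene_id} exceeds scaffold bounds")
        cls = classes[gene.scaffold]
        cid = codon_id[gene.scaffold]
        coff = codon_offset[gene.scaffold]

        span_sites = np.arange(lo, hi)
        intronable = cls[span_sites] == INTERGENIC
        cls[span_sites[intronable]] = INTRON
        if gene.exon_segments:
            cds_set = np.zeros(hi - lo, dtype=bool)
            for s, e in gene.cds_segments:
                cds_set[max(s, lo) - lo : min(e, hi) - lo] = True
            for s, e in gene.exon_segments:
                s, e = max(s, lo), min(e, hi)
                if e <= s:
                    continue
                rel = np.arange(s, e)
                utr = rel[~cds_set[rel - lo] & (cls[rel] == INTRON)]
                cls[utr] = GENIC_NC

        tpos = _transcription_positions(gene)
        phase = gene.phase % 3
        if phase:
            trimmed = tpos[:phase]
            keep = cls[trimmed] == INTRON  # avoid clobbering other genes
            cls[trimmed[keep]] = MASKED
            qc["phase_trimmed_sites"] += int(phase)
            tpos = tpos[phase:]
        if len(tpos) % 3 != 0:
            warnings.warn(
                f"gene {gene.gene_id}: CDS length {len(tpos)} not a multiple of 3 "
                "after phase trimming; gene skipped",
                stacklevel=2,
            )
            qc["genes_skipped_bad_length"] += 1
            continue
        if len(tpos) == 0:
            continue

        gene_idx = len(gene_ids)
        gene_ids.append(gene.gene_id)
        sites3 = tpos.reshape(-1, 3)
        base_codes = seq[sites3]
        if gene.strand == "-":
            base_codes = np.where(base_codes < 4, 3 - base_codes, base_codes)
        cidx = codon_index(base_codes)
        is_stop = (cidx >= 0) & STOP_CODON[np.clip(cidx, 0, 63)]

        n_codons_here = sites3.shape[0]
        start_cid = len(codons_list)
        valid_here = np.ones(n_codons_here, dtype=bool)

        for j in range(n_codons_here):
            sites = sites3[j]
            conflict = cid[sites] >= 0
            if conflict.any():
                # overlapping annotation: mask the shared sites, invalidate
                # both the previously assigned codons and this one
                for s in sites[conflict]:
                    old = cid[s]
                    if 0 <= old < len(codon_valid_list):
                        codon_valid_list[old] = False
                    cls[s] = MASKED
                qc["sites_overlap_masked"] += int(conflict.sum())
                valid_here[j] = False

        terminal_stop = is_stop[-1] if n_codons_here else False
        internal_stop = is_stop.copy()
        if terminal_stop:
            internal_stop[-1] = False
        qc["codons_internal_stop"] += int(internal_stop.sum())
        qc["codons_with_n"] += int((cidx < 0).sum())
        valid_here &= cidx >= 0
        valid_here &= ~is_stop

        for j in range(n_codons_here):
            sites = sites3[j]
            this_cid = start_cid + j
            free = cid[sites] < 0
            if is_stop[j] or cidx[j] < 0:
                # terminal/internal stop codons and ambiguous codons carry no
                # coding-site semantics: mask (without clobbering other genes)
                cls[sites[free]] = MASKED
            else:
                cls[sites[free]] = np.array([POS1, POS2, POS3], np.int8)[free]
            cid[sites[free]] = this_cid
            coff[sites[free]] = np.arange(3, dtype=np.int8)[free]
            codons_list.append(int(cidx[j]) if cidx[j] >= 0 else -1)
            codon_gene_list.append(gene_idx)
            codon_strand_list.append(gene.strand)
            codon_scaf_list.append(scaf_index[gene.scaffold])
            codon_sites_list.append(sites)
            codon_valid_list.append(bool(valid_here[j]))

    codons = np.asarray(codons_list, dtype=np.int16)
    codon_valid = np.asarray(codon_valid_list, dtype=bool)
    codon_sites = (
        np.asarray(codon_sites_list, dtype=np.int64)
        if codon_sites_list
        else np.empty((0, 3), np.int64)
    )

    fourfold = {name: np.zeros(len(bundle.scaffolds[name]), bool) for name in scaffold_names}
    if len(codons):
        ff = codon_valid & (codons >= 0) & FOURFOLD_CODON[np.clip(codons, 0, 63)]
        scafs = np.asarray(codon_scaf_list, dtype=np.int64)
        for si, name in enumerate(scaffold_names):
            sel = ff & (scafs == si)
            third = codon_sites[sel, 2]
            # only where the site still belongs to this codon and is coding
            ok = classes[name][third] == POS3
            fourfold[name][third[ok]] = True

    return SiteClassMap(
        classes=classes,
        fourfold=fourfold,
        n_mask=n_mask,
        codon_id=codon_id,
        codon_offset=codon_offset,
        codons=codons,
        codon_gene=np.asarray(codon_gene_list, dtype=np.int32),
        codon_strand=np.asarray(codon_strand_list, dtype="U1"),
        codon_scaffold=np.asarray(codon_scaf_list, dtype=np.int32),
        codon_sites=codon_sites,
        codon_valid=codon_valid,
        scaffold_names=scaffold_names,
        gene_ids=gene_ids,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# Window covariates
# ---------------------------------------------------------------------------


def _window_sums(values: np.ndarray, widx: np.ndarray, n_win: int) -> np.ndarray:
    return np.bincount(widx, weights=values, minlength=n_win)[:n_win]


def gene_density(scmap: SiteClassMap, grid: WindowGrid) -> pd.DataFrame:
    """Per-window gene density: coding sites / sites with sequence information.

    The denominator excludes assembly gaps (N) but includes everything else,
    repeats included.  Windows with zero non-N sites get a missing value.
    """
    frames = []
    for scaf in grid.scaffold_lengths:
        cls = scmap.classes[scaf]
        nn = scmap.n_mask[scaf]
        n_win = grid.n_windows(scaf)
        widx = np.arange(len(cls)) // grid.window_size
        coding = np.isin(cls, CODING_CLASSES).astype(float)
        non_n = (~nn).astype(float)
        num = _window_sums(coding, widx, n_win)
        den = _window_sums(non_n, widx, n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        win = grid.windows(scaf)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": [w[0] for w in win],
                    "end": [w[1] for w in win],
                    "gene_density": dens,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gc_content(codes: np.ndarray, mask: np.ndarray | None = None) -> float:
    """GC fraction (#G+#C over #ACGT) of selected sites; NaN if none selected."""
    if mask is not None:
        codes = codes[mask]
    counts = np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return float("nan")
    return float((counts[1] + counts[2]) / total)


def window_gc(bundle: GenomeBundle, grid: WindowGrid) -> pd.DataFrame:
    """GC content per window (Ns excluded from the denominator)."""
    frames = []
    for scaf in grid.scaffold_lengths:
        seq = bundle.scaffolds[scaf]
        n_win = grid.n_windows(scaf)
        widx = np.arange(len(seq)) // grid.window_size
        is_gc = ((seq == 1) | (seq == 2)).astype(float)
        is_acgt = (seq < 4).astype(float)
        num = _window_sums(is_gc, widx, n_win)
        den = _window_sums(is_acgt, widx, n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        win = grid.windows(scaf)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": [w[0] for w in win],
                    "end": [w[1] for w in win],
                    "gc": gc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def class_gc(bundle: GenomeBundle, scmap: SiteClassMap) -> pd.DataFrame:
    """GC content per site class (plus the 4D subset), over the whole genome."""
    rows = []
    selectors = {CLASS_NAMES[c]: c for c in (POS1, POS2, POS3, INTRON, INTERGENIC)}
    for label, code in selectors.items():
        num = den = 0
        for scaf, seq in bundle.scaffolds.items():
            sel = scmap.classes[scaf] == code
            sub = seq[sel]
            counts = np.bincount(sub[sub < 4], minlength=4)
            num += counts[1] + counts[2]
            den += counts.sum()
        rows.append((label, num / den if den else np.nan, int(den)))
    num = den = 0
    for scaf, seq in bundle.scaffolds.items():
        sub = seq[scmap.fourfold[scaf]]
        counts = np.bincount(sub[sub < 4], minlength=4)
        num += counts[1] + counts[2]
        den += counts.sum()
    rows.append(("fourfold", num / den if den else np.nan, int(den)))
    return pd.DataFrame(rows, columns=["site_class", "gc", "n_sites"])


def window_rho(track: pd.DataFrame, grid: WindowGrid) -> pd.DataFrame:
    """Length-weighted mean rho per window.

    Track intervals may leave gaps (treated as no data); a window with no
    overlapping data gets a missing value.  Negative rho is rejected.
    """
    if (track["rho"] < 0).any():
        raise ValueError("rho track contains negative values")
    frames = []
    for scaf in grid.scaffold_lengths:
        n_win = grid.n_windows(scaf)
        wsum = np.zeros(n_win)
        wlen = np.zeros(n_win)
        sub = track[track["scaffold"] == scaf]
        for start, end, rho in zip(sub["start"], sub["end"], sub["rho"]):
            start = max(int(start), 0)
            end = min(int(end), grid.scaffold_lengths[scaf])
            w = start // grid.window_size
            while start < end:
                w_end = min((w + 1) * grid.window_size, end)
                span = w_end - start
                wsum[w] += rho * span
                wlen[w] += span
                start = w_end
                w += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(wlen > 0, wsum / np.maximum(wlen, 1), np.nan)
        win = grid.windows(scaf)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": [w[0] for w in win],
                    "end": [w[1] for w in win],
                    "rho": mean,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def window_covariates(
    bundle: GenomeBundle,
    scmap: SiteClassMap,
    grid: WindowGrid,
    rho_track: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join gene density, GC and (optionally) window-averaged rho."""
    cov = gene_density(scmap, grid).merge(
        window_gc(bundle, grid), on=["scaffold", "start", "end"]
    )
    if rho_track is not None:
        cov = cov.merge(window_rho(rho_track, grid), on=["scaffold", "start", "end"])
    else:
        cov["rho"] = np.nan
    return cov


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_site_class_map(scmap: SiteClassMap, path) -> None:
    """Write the site-class map as a run-length-encoded TSV."""
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tsite_class\tfourfold\n")
        for scaf in scmap.scaffold_names:
            cls = scmap.classes[scaf].astype(np.int16)
            ff = scmap.fourfold[scaf]
            combo = cls * 2 + ff
            change = np.flatnonzero(np.diff(combo)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(cls)]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{scaf}\t{s}\t{e}\t{CLASS_NAMES[int(cls[s])]}\t{int(ff[s])}\n"
                )
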