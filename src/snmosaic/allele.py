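"""Per-cell expressed-allele genotyping from barcoded 5' reads.

A 100-bp window around a gene's start codon serves as the reference; reads
are matched to it by exhaustive ungapped alignment on both strands, the
codon at the matched position is read off and classified as wild-type (ATG)
or mutant (TTG), read votes are collapsed per UMI, and each cell barcode is
called by strict UMI majority. At a 100-nt reference, exhaustive matching is
exact and needs no index; the variant is a substitution, so gaps are not
modeled.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

WT_CODON = "ATG"
MUT_CODON = "TTG"
WINDOW = 100
FLANK = 50

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class BoundaryError(ValueError):
    pass


@dataclass(frozen=True)
class MiniReference:
    """100-nt start-codon window: 50 nt upstream of the codon and 50 nt from
    the codon start onward, codon occupying offsets 50-52."""
    gene_id: str
    sequence: str
    codon_offset: int
    wt_codon: str = WT_CODON
    mut_codon: str = MUT_CODON

    @property
    def mut_sequence(self) -> str:
        o = self.codon_offset
        return self.sequence[:o] + self.mut_codon + self.sequence[o + 3:]


def build_mini_reference(gene_sequence: str, start_codon_position: int,
                         gene_id: str = "gene",
                         wt_codon: str = WT_CODON,
                         mut_codon: str = MUT_CODON) -> MiniReference:
    """Cut the [start-50, start+50) window around a validated start codon."""
    gene_sequence = gene_sequence.upper()
    if start_codon_position < FLANK:
        raise BoundaryError(
            f"need {FLANK} nt upstream of the codon, only {start_codon_position} available")
    if len(gene_sequence) - start_codon_position < FLANK:
        raise BoundaryError(
            f"need {FLANK} nt from the codon start onward, only "
            f"{len(gene_sequence) - start_codon_position} available")
    codon = gene_sequence[start_codon_position:start_codon_position + 3]
    if codon != wt_codon:
        raise ValueError(f"expected {wt_codon} at position {start_codon_position}, found {codon}")
    window = gene_sequence[start_codon_position - FLANK:start_codon_position + FLANK]
    return MiniReference(gene_id=gene_id, sequence=window, codon_offset=FLANK,
                         wt_codon=wt_codon, mut_codon=mut_codon)


@dataclass(frozen=True)
class ReadMatch:
    offset: int       # read start relative to reference start (may be negative)
    strand: str       # '+' or '-'
    n_mismatch: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_read(read_sequence: str, ref: MiniReference, max_mismatch: int = 3,
               min_codon_cover: bool = True, min_overlap: int = 30) -> ReadMatch | None:
    """Best ungapped placement of a read on the mini-reference, both strands.

    Mismatches at the three codon positions are never counted against the
    threshold (the variant itself must not penalize placement). Ties prefer
    the plus strand, then the smaller offset.
    """
    read_sequence = read_sequence.upper()
    if len(read_sequence) < 20:
        return None
    ref_arr = _encode(ref.sequence)
    best: ReadMatch | None = None
    for strand, seq in (("+", read_sequence), ("-", revcomp(read_sequence))):
        arr = _encode(seq)
        m = _best_offset(arr, ref_arr, ref.codon_offset, max_mismatch,
                         min_codon_cover, min_overlap)
        if m is not None:
            cand = ReadMatch(offset=m[0], strand=strand, n_mismatch=m[1])
            if best is None or cand.n_mismatch < best.n_mismatch:
                best = cand
    return best


def _best_offset(read: np.ndarray, ref: np.ndarray, codon_offset: int,
                 max_mismatch: int, min_codon_cover: bool,
                 min_overlap: int) -> tuple[int, int] | None:
    L, R = len(read), len(ref)
    best = None
    for off in range(-(L - min_overlap), R - min_overlap + 1):
        lo = max(0, off)
        hi = min(R, off + L)
        if hi - lo < min_overlap:
            continue
        if min_codon_cover and not (off <= codon_offset and off + L >= codon_offset + 3):
            continue
        seg_ref = ref[lo:hi]
        seg_read = read[lo - off:hi - off]
        mm = seg_ref != seg_read
        # codon positions are exempt from the mismatch count
        clo, chi = codon_offset - lo, codon_offset + 3 - lo
        if clo >= 0 and chi <= mm.size:
            n_mm = int(mm.sum() - mm[clo:chi].sum())
        else:
            n_mm = int(mm.sum())
        if n_mm <= max_mismatch and (best is None or n_mm < best[1]):
            best = (off, n_mm)
            if n_mm == 0:
                break
    return best


# ---------------------------------------------------------------------------
# read ingestion

@dataclass
class TaggedRead:
    barcode: str | None
    umi: str | None
    sequence: str
    quality: str | None = None


_NAME_RE = re.compile(r"_CB:(?P<cb>[^_\s]+)_UMI:(?P<umi>[^_\s]+)")


def _open_text(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a 4-line FASTQ, gzip or plain."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0].rstrip("\n"), seq, qual


def read_tagged_fastq(path) -> Iterator[TaggedRead]:
    """Reads whose name carries ``_CB:<barcode>_UMI:<umi>`` tags."""
    for name, seq, qual in iter_fastq(path):
        m = _NAME_RE.search(name)
        if m:
            yield TaggedRead(m.group("cb"), m.group("umi"), seq, qual)
        else:
            yield TaggedRead(None, None, seq, qual)


def read_paired_fastq(r1_path, r2_path, barcode_len: int = 16,
                      umi_len: int = 10) -> Iterator[TaggedRead]:
    """10x-style pairing: R1 = 16-nt barcode + 10-nt UMI, R2 = cDNA."""
    for (n1, s1, _), (_, s2, q2) in zip(iter_fastq(r1_path), iter_fastq(r2_path)):
        if len(s1) < barcode_len + umi_len:
            yield TaggedRead(None, None, s2, q2)
        else:
            yield TaggedRead(s1[:barcode_len], s1[barcode_len:barcode_len + umi_len],
                             s2, q2)


def read_tsv_reads(path) -> Iterator[TaggedRead]:
    """Pre-extracted (barcode, umi, sequence) TSV; header optional."""
    with _open_text(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[0].lower() == "barcode":
                continue
            yield TaggedRead(parts[0], parts[1], parts[2])


# ---------------------------------------------------------------------------
# counting and calling

@dataclass
class AlleleCount:
    barcode: str
    n_wt_umi: int = 0
    n_mut_umi: int = 0
    n_ambiguous_umi: int = 0
    n_reads_matched: int = 0


MIN_CODON_QUALITY = 20


def _codon_of_match(read: TaggedRead, match: ReadMatch, ref: MiniReference,
                    min_quality: int = MIN_CODON_QUALITY) -> str:
    seq = read.sequence.upper() if match.strand == "+" else revcomp(read.sequence.upper())
    start = ref.codon_offset - match.offset
    codon = seq[start:start + 3]
    if read.quality is not None and len(read.quality) == len(read.sequence):
        qual = read.quality if match.strand == "+" else read.quality[::-1]
        phred = [ord(q) - 33 for q in qual[start:start + 3]]
        if any(p < min_quality for p in phred):
            return "LOWQ"
    return codon


def count_alleles(reads: Iterable[TaggedRead], ref: MiniReference,
                  max_mismatch: int = 3,
                  min_codon_quality: int = MIN_CODON_QUALITY,
                  ) -> tuple[list[AlleleCount], dict]:
    """Match reads, classify codons, collapse per UMI, tally per barcode.

    Per (barcode, UMI) the majority codon class over its reads decides the
    UMI's vote; a tie, or a majority that is neither WT nor MUT codon, makes
    the UMI ambiguous. Reads without barcode/UMI are skipped and counted.
    """
    votes: dict[str, dict[str, list[str]]] = {}
    matched_per_barcode: dict[str, int] = {}
    stats = {"n_reads": 0, "n_skipped_untagged": 0, "n_matched": 0}
    for read in reads:
        stats["n_reads"] += 1
        if not read.barcode or not read.umi:
            stats["n_skipped_untagged"] += 1
            continue
        m = match_read(read.sequence, ref, max_mismatch=max_mismatch)
        if m is None:
            continue
        stats["n_matched"] += 1
        matched_per_barcode[read.barcode] = matched_per_barcode.get(read.barcode, 0) + 1
        codon = _codon_of_match(read, m, ref, min_codon_quality)
        cls = ("WT" if codon == ref.wt_codon
               else "MUT" if codon == ref.mut_codon else "OTHER")
        votes.setdefault(read.barcode, {}).setdefault(read.umi, []).append(cls)

    counts = []
    for barcode, umis in votes.items():
        ac = AlleleCount(barcode=barcode,
                         n_reads_matched=matched_per_barcode.get(barcode, 0))
        for classes in umis.values():
            n_wt = classes.count("WT")
            n_mut = classes.count("MUT")
            n_other = len(classes) - n_wt - n_mut
            top = max(n_wt, n_mut, n_other)
            if n_wt == top and n_mut < top and n_other < top:
                ac.n_wt_umi += 1
            elif n_mut == top and n_wt < top and n_other < top:
                ac.n_mut_umi += 1
            else:
                ac.n_ambiguous_umi += 1
        counts.append(ac)
    return counts, stats


@dataclass
class GenotypeCall:
    barcode: str
    call: str            # WT | MUT | AMBIGUOUS | NONE
    wt_fraction: float   # NaN when NONE


def call_genotypes(counts: Iterable[AlleleCount]) -> list[GenotypeCall]:
    """Strict UMI-majority call per barcode."""
    calls = []
    for c in counts:
        if min(c.n_wt_umi, c.n_mut_umi, c.n_ambiguous_umi) < 0:
            raise ValueError(f"negative UMI count for barcode {c.barcode}")
        total = c.n_wt_umi + c.n_mut_umi
        if total == 0:
            calls.append(GenotypeCall(c.barcode, "NONE", float("nan")))
            continue
        frac = c.n_wt_umi / total
        if c.n_wt_umi > c.n_mut_umi:
            call = "WT"
        elif c.n_mut_umi > c.n_wt_umi:
            call = "MUT"
        else:
            call = "AMBIGUOUS"
        calls.append(GenotypeCall(c.barcode, call, frac))
    return calls


def genotype_table(counts: list[AlleleCount]) -> pd.DataFrame:
    """Joined per-barcode counts + calls as the output TSV layout."""
    calls = {c.barcode: c for c in call_genotypes(counts)}
    rows = [{
        "barcode": c.barcode, "n_wt_umi": c.n_wt_umi, "n_mut_umi": c.n_mut_umi,
        "n_ambiguous_umi": c.n_ambiguous_umi, "n_reads_matched": c.n_reads_matched,
        "call": calls[c.barcode].call, "wt_fraction": calls[c.barcode].wt_fraction,
    } for c in counts]
    return pd.DataFrame(rows, columns=[
        "barcode", "n_wt_umi", "n_mut_umi", "n_ambiguous_umi",
        "n_reads_matched", "call", "wt_fraction"])


def genotype_fastq(fastq_path, gene_fasta: str | Path | None = None,
                   gene_sequence: str | None = None, codon_pos: int | None = None,
                   wt_codon: str = WT_CODON, mut_codon: str = MUT_CODON,
                   max_mismatch: int = 3, paired_r1=None) -> pd.DataFrame:
    """End-to-end genotyping of a FASTQ file; see ``count_alleles``."""
    if gene_sequence is None:
        from Bio import SeqIO
        rec = next(SeqIO.parse(str(gene_fasta), "fasta"))
        gene_sequence = str(rec.seq)
    ref = build_mini_reference(gene_sequence, codon_pos,
                               wt_codon=wt_codon, mut_codon=mut_codon)
    if paired_r1 is not None:
        reads = read_paired_fastq(paired_r1, fastq_path)
    else:
        reads = read_tagged_fastq(fastq_path)
    counts, _ = count_alleles(reads, ref, max_mismatch=max_mismatch)
    return genotype_table(counts)
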