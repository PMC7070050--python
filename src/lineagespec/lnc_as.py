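"""lncRNA consensus calling and alternative-splicing event classification.

lncRNA candidates are assembled transcripts that survive two filters
(length >= 200 nt; single-exon transcripts overlapping a same-strand coding
exon are removed), are placed in a genomic context (sense / antisense /
intergenic relative to coding genes), and are called lncRNA when at least
``min_votes`` of ``n_scorers`` coding-potential scorers vote noncoding
(the study rule: >= 4 of 5 programs).  Three scorers are built in — longest
ORF, hexamer usage bias, and in-frame stop density — and external per-tool
calls can be supplied as extra vote columns via TSV.

Alternative-splicing events are classified from pairwise exon-chain
comparison of expressed isoforms of one gene into the four basic types —
exon skipping, alternative acceptor site, alternative donor site, intron
retention — plus a complex catch-all.  Donor and acceptor are the intron's
5' and 3' boundaries in transcription orientation, so classification is
strand-aware.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "ASEvent",
    "LncCall",
    "filter_candidates",
    "classify_context",
    "vote_lncRNA",
    "builtin_scorers",
    "detect_as_events",
    "compare_across_cells",
    "longest_orf_codons",
    "build_hexamer_table",
    "write_gtf",
    "read_gtf",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Transcript models


@dataclass
class TranscriptModel:
    """Exon chain on one strand; intervals are 1-based inclusive, sorted."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "candidate"  # coding | candidate | noncoding

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = [tuple(e) for e in self.exons]
        if not ex:
            raise ValueError(f"{self.transcript_id}: empty exon chain")
        ex.sort()
        for s, e in ex:
            if s > e or s < 1:
                raise ValueError(
                    f"{self.transcript_id}: malformed exon ({s}, {e})"
                )
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping/abutting exons"
                )
        self.exons = ex

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def overlaps_exonic(self, other: "TranscriptModel") -> bool:
        """Any exon-exon overlap with another transcript (same chrom)."""
        if self.chrom != other.chrom:
            return False
        for s1, e1 in self.exons:
            for s2, e2 in other.exons:
                if s1 <= e2 and s2 <= e1:
                    return True
        return False


@dataclass
class ASEvent:
    gene_id: str
    isoform_a: str
    isoform_b: str
    type: str  # exon_skipping | alt_acceptor | alt_donor | intron_retention | complex
    region: tuple[int, int]


@dataclass
class LncCall:
    transcript_id: str
    context: str  # sense | antisense | intergenic
    votes: list[bool]
    is_lncRNA: bool


# ---------------------------------------------------------------------------
# lncRNA candidate filtering and context


def filter_candidates(
    transcripts: list[TranscriptModel],
    coding: list[TranscriptModel],
    min_len: int = 200,
) -> list[TranscriptModel]:
    """Apply the lncRNA candidate filters.

    Removes transcripts shorter than ``min_len`` and single-exon transcripts
    with exonic overlap to a same-strand coding transcript.  Multi-exon
    transcripts overlapping coding genes are retained (they become "sense"
    candidates downstream).
    """
    out = []
    for t in transcripts:
        if t.length < min_len:
            continue
        if len(t.exons) == 1 and any(
            c.strand == t.strand and t.overlaps_exonic(c) for c in coding
        ):
            continue
        out.append(t)
    return out


def classify_context(
    candidate: TranscriptModel, coding: list[TranscriptModel]
) -> str:
    """sense / antisense / intergenic relative to coding transcripts."""
    same = any(
        c.strand == candidate.strand and candidate.overlaps_exonic(c)
        for c in coding
    )
    if same:
        return "sense"
    opposite = any(
        c.strand != candidate.strand and candidate.overlaps_exonic(c)
        for c in coding
    )
    return "antisense" if opposite else "intergenic"


def vote_lncRNA(votes, n_scorers: int = 5, min_votes: int = 4) -> bool:
    """Consensus rule: noncoding iff >= min_votes of n_scorers agree."""
    votes = list(votes)
    if len(votes) != n_scorers:
        raise ValueError(
            f"expected {n_scorers} votes, got {len(votes)}"
        )
    return sum(bool(v) for v in votes) >= min_votes


# ---------------------------------------------------------------------------
# Built-in coding-potential scorers (each returns a noncoding boolean)


def longest_orf_codons(seq: str) -> int:
    """Longest ATG-initiated ORF over all 6 frames, in codons (stop incl.).

    An ORF running off the end of the sequence counts its complete codons.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            pos = frame
            open_start = None
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if open_start is None:
                    if codon == "ATG":
                        open_start = pos
                elif codon in STOP_CODONS:
                    best = max(best, (pos + 3 - open_start) // 3)
                    open_start = None
                pos += 3
            if open_start is not None:
                best = max(best, (len(s) - open_start) // 3)
    return best


def build_hexamer_table(seqs: list[str], pseudocount: float = 1.0) -> np.ndarray:
    """Hexamer frequency table (4096,) from training sequences."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.full(4096, pseudocount)
    for seq in seqs:
        seq = seq.upper()
        code = 0
        valid = 0
        for ch in seq:
            if ch not in idx:
                code, valid = 0, 0
                continue
            code = ((code << 2) | idx[ch]) & 0xFFF
            valid += 1
            if valid >= 6:
                counts[code] += 1
    return counts / counts.sum()


def hexamer_score(seq: str, coding_freq: np.ndarray, noncoding_freq: np.ndarray) -> float:
    """Mean log-ratio of hexamer frequencies (coding over noncoding)."""
    idx = {b: i for i, b in enumerate("ACGT")}
    seq = seq.upper()
    logratio = np.log(coding_freq) - np.log(noncoding_freq)
    total, nhex = 0.0, 0
    code, valid = 0, 0
    for ch in seq:
        if ch not in idx:
            code, valid = 0, 0
            continue
        code = ((code << 2) | idx[ch]) & 0xFFF
        valid += 1
        if valid >= 6:
            total += logratio[code]
            nhex += 1
    return total / nhex if nhex else 0.0


def best_frame_stop_density(seq: str) -> float:
    """In-frame stop density of the best forward reading frame.

    The best frame is the forward frame carrying the longest ATG-initiated
    ORF (frame 0 when no ORF exists); the density is stops per codon over
    the whole sequence in that frame.  A coding transcript has a long
    stop-free stretch in its ORF frame, a random sequence ~3/64 per codon in
    every frame.
    """
    seq = seq.upper()
    best_frame, best_orf = 0, 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        start, longest = None, 0
        for idx, c in enumerate(codons):
            if start is None:
                if c == "ATG":
                    start = idx
            elif c in STOP_CODONS:
                longest = max(longest, idx - start + 1)
                start = None
        if start is not None:
            longest = max(longest, len(codons) - start)
        if longest > best_orf:
            best_orf, best_frame = longest, frame
    codons = [
        seq[i : i + 3] for i in range(best_frame, len(seq) - 2, 3)
    ]
    if not codons:
        raise ValueError("sequence too short for a codon")
    return sum(c in STOP_CODONS for c in codons) / len(codons)


def builtin_scorers(
    seq: str,
    hexamer_tables: tuple[np.ndarray, np.ndarray] | None = None,
    orf_min_codons: int = 100,
    stop_density_max: float = 0.03,
) -> dict[str, bool]:
    """Run the built-in coding-potential scorers on one transcript sequence.

    Returns a dict of noncoding votes: ``orf`` (longest ORF < orf_min_codons
    codons), ``hexamer`` (mean hexamer log-ratio < 0; requires training
    tables (coding_freq, noncoding_freq)), and ``stop_density`` (best-frame
    in-frame stop density > stop_density_max).
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence alphabet must be ACGTN, found {sorted(bad)}")
    votes = {
        "orf": longest_orf_codons(seq) < orf_min_codons,
        "stop_density": best_frame_stop_density(seq) > stop_density_max,
    }
    if hexamer_tables is not None:
        coding_freq, noncoding_freq = hexamer_tables
        votes["hexamer"] = hexamer_score(seq, coding_freq, noncoding_freq) < 0.0
    return votes


def read_external_votes(tsv) -> pd.DataFrame:
    """External per-tool noncoding votes: transcript_id + boolean columns."""
    tab = pd.read_csv(tsv, sep="\t", index_col=0)
    return tab.astype(bool)


# ---------------------------------------------------------------------------
# Alternative-splicing classification


def _clip_chain(
    exons: list[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    out = []
    for s, e in exons:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


def _components(intervals: list[tuple[int, int, str]]):
    """Group (start, end, owner) intervals into overlap-connected components."""
    ivs = sorted(intervals)
    comps = []
    cur: list[tuple[int, int, str]] = []
    cur_end = -1
    for iv in ivs:
        if cur and iv[0] > cur_end:
            comps.append(cur)
            cur = []
        cur.append(iv)
        cur_end = max(cur_end, iv[1])
    if cur:
        comps.append(cur)
    return comps


def _classify_component(
    comp, a: TranscriptModel, b: TranscriptModel
) -> str:
    strand = a.strand
    ia = sorted((s, e) for s, e, who in comp if who == "A")
    ib = sorted((s, e) for s, e, who in comp if who == "B")
    if len(ia) == 1 and len(ib) == 0 or len(ia) == 0 and len(ib) == 1:
        # an intron of one isoform entirely exonic in the other
        intron = (ia or ib)[0]
        host = b if ia else a
        if any(s <= intron[0] and intron[1] <= e for s, e in host.exons):
            return "intron_retention"
        return "complex"
    if len(ia) == 1 and len(ib) == 1:
        (s1, e1), (s2, e2) = ia[0], ib[0]
        if e1 == e2 and s1 != s2:
            # introns share the 3' genomic end, differ at genomic start:
            # on + the start is the intron 5' (donor) side
            return "alt_donor" if strand == "+" else "alt_acceptor"
        if s1 == s2 and e1 != e2:
            return "alt_acceptor" if strand == "+" else "alt_donor"
        return "complex"
    if {len(ia), len(ib)} == {2, 1}:
        two, one = (ia, ib[0]) if len(ia) == 2 else (ib, ia[0])
        with_exon = a if len(ia) == 2 else b
        (s1, e1), (s2, e2) = two
        skipped = (e1 + 1, s2 - 1)
        if (
            one[0] == s1
            and one[1] == e2
            and skipped in with_exon.exons
        ):
            return "exon_skipping"
        return "complex"
    return "complex"


def classify_pair(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """Classify the local splice differences between two isoforms."""
    if a.strand != b.strand or a.chrom != b.chrom:
        raise ValueError(
            f"isoforms {a.transcript_id}/{b.transcript_id} are not on the "
            "same chromosome and strand"
        )
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo > hi:
        return []
    ca = TranscriptModel(
        a.transcript_id, a.gene_id, a.chrom, a.strand, _clip_chain(a.exons, lo, hi)
    )
    cb = TranscriptModel(
        b.transcript_id, b.gene_id, b.chrom, b.strand, _clip_chain(b.exons, lo, hi)
    )
    set_a, set_b = set(ca.introns()), set(cb.introns())
    diff = [(s, e, "A") for s, e in set_a - set_b]
    diff += [(s, e, "B") for s, e in set_b - set_a]
    events = []
    for comp in _components(diff):
        typ = _classify_component(comp, ca, cb)
        region = (min(s for s, _, _ in comp), max(e for _, e, _ in comp))
        events.append(
            ASEvent(a.gene_id, a.transcript_id, b.transcript_id, typ, region)
        )
    return events


def detect_as_events(
    isoforms: list[TranscriptModel],
    fpkm: pd.DataFrame | None = None,
    cell_type: str | None = None,
    min_fpkm: float = 1.0,
) -> list[ASEvent]:
    """Pairwise AS events among the expressed isoforms of one gene.

    When ``fpkm`` (transcript x cell-type mean FPKM) and ``cell_type`` are
    given, only isoforms with FPKM >= min_fpkm in that cell type enter the
    comparison.
    """
    if fpkm is not None and cell_type is not None:
        isoforms = [
            t
            for t in isoforms
            if t.transcript_id in fpkm.index
            and fpkm.at[t.transcript_id, cell_type] >= min_fpkm
        ]
    if len(isoforms) < 2:
        return []
    genes = {t.gene_id for t in isoforms}
    if len(genes) != 1:
        raise ValueError(f"isoforms span multiple genes: {sorted(genes)}")
    events = []
    for a, b in itertools.combinations(isoforms, 2):
        events.extend(classify_pair(a, b))
    return events


def compare_across_cells(
    isoform_sets: dict[str, set[str]],
) -> dict[str, set[str]]:
    """Cell-type-specific and lineage-maintained isoform sets.

    Specific = present in a cell type, absent from its counterpart
    (AC vs BC, 32E vs 32S); lineage-maintained = specific to the lineage's
    cell type at both stages.
    """
    counterparts = {"AC": "BC", "BC": "AC", "32E": "32S", "32S": "32E"}
    unknown = set(isoform_sets) - set(counterparts)
    if unknown:
        raise ValueError(f"unknown cell type keys: {sorted(unknown)}")
    out: dict[str, set[str]] = {}
    for ct, other in counterparts.items():
        if ct in isoform_sets and other in isoform_sets:
            out[f"{ct}_specific"] = isoform_sets[ct] - isoform_sets[other]
    if {"AC_specific", "32E_specific"} <= out.keys():
        out["ACL_maintained"] = out["AC_specific"] & out["32E_specific"]
    if {"BC_specific", "32S_specific"} <= out.keys():
        out["BCL_maintained"] = out["BC_specific"] & out["32S_specific"]
    return out


# ---------------------------------------------------------------------------
# GTF interchange (1-based inclusive)


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'biotype "{t.biotype}";'
            )
            fh.write(
                f"{t.chrom}\tlineagespec\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tlineagespec\texon\t{s}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features of a GTF into transcript models."""
    import gffutils

    chains: dict[str, dict] = {}
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        tid = feat.attributes["transcript_id"][0]
        rec = chains.setdefault(
            tid,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": (feat.attributes.get("biotype") or ["candidate"])[0],
                "exons": [],
            },
        )
        rec["exons"].append((feat.start, feat.end))
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"],
        )
        for tid, rec in chains.items()
    ]
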