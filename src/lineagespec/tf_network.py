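"""Promoter-window motif scanning and TF regulatory-network assembly.

TF binding sites are modelled as position weight matrices scanned over the
promoter window −500..+100 relative to each gene's TSS (both strands,
log-odds against a uniform background).  A TF is linked to a target gene
when three lines of evidence agree: the TF's motif is enriched among the DEG
set (hypergeometric, BH FDR < 0.05), the target's promoter window carries a
motif hit, and the TF and target expression profiles are coexpressed
(Pearson r > 0.87 across cell types, the cutoff used for cluster
coexpression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, enrich

__all__ = [
    "Motif",
    "MotifHit",
    "PromoterSet",
    "promoter_window",
    "scan_promoters",
    "tf_motif_enrichment",
    "coexpression_filter",
    "build_network",
]

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

WINDOW_UP = 500  # nt upstream of the TSS
WINDOW_DOWN = 100  # nt downstream


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A PWM in probability form (rows = positions, columns = A,C,G,T)."""

    tf_id: str
    matrix: np.ndarray
    consensus: str = ""
    threshold: float | None = None  # absolute log-odds cutoff
    threshold_fraction: float = 0.8  # of max score, when threshold is None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be length x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("motif columns must sum to 1 (probability form)")
        if not self.consensus:
            self.consensus = "".join(
                BASES[i] for i in self.matrix.argmax(axis=1)
            )

    @classmethod
    def from_consensus(
        cls, tf_id: str, consensus: str, match_prob: float = 0.91
    ) -> "Motif":
        """Sharp PWM putting ``match_prob`` on the consensus base."""
        off = (1.0 - match_prob) / 3.0
        mat = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            mat[i, _IDX[b]] = match_prob
        return cls(tf_id=tf_id, matrix=mat, consensus=consensus)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def logodds(self) -> np.ndarray:
        """Log2-odds against a uniform background (N contributes 0)."""
        with np.errstate(divide="ignore"):
            return np.log2(np.maximum(self.matrix, 1e-12) / 0.25)

    def max_score(self) -> float:
        return float(self.logodds().max(axis=1).sum())

    def score_cutoff(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return self.threshold_fraction * self.max_score()

    def score(self, seq: str) -> float:
        """Log-odds of one window (len == motif length); N scores 0."""
        lo = self.logodds()
        return float(
            sum(
                lo[i, _IDX[b]] if b in _IDX else 0.0
                for i, b in enumerate(seq)
            )
        )


@dataclass
class MotifHit:
    tf_id: str
    gene_id: str
    position: int  # relative to the TSS (0 = TSS), transcription-oriented
    strand: str  # genomic strand of the matching sequence
    score: float


def promoter_window(
    tss: int, strand: str, upstream: int = WINDOW_UP, downstream: int = WINDOW_DOWN
) -> tuple[int, int]:
    """Genomic 1-based inclusive interval of the promoter window.

    On the + strand this is [tss - upstream, tss + downstream]; on the −
    strand the mirror image [tss - downstream, tss + upstream].  Clipped at 1.
    """
    if tss < 1:
        raise ValueError("tss must be 1-based (>= 1)")
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise ValueError(f"unknown strand symbol: {strand!r}")
    return max(lo, 1), hi


@dataclass
class Promoter:
    """One gene's promoter window: forward-strand genomic sequence + frame."""

    gene_id: str
    chrom: str
    tss: int  # 1-based genomic
    strand: str
    window_start: int  # 1-based inclusive, genomic
    window_end: int
    seq: str  # forward-strand sequence of [window_start, window_end]

    def __post_init__(self) -> None:
        expected = self.window_end - self.window_start + 1
        if len(self.seq) != expected:
            raise ValueError(
                f"promoter sequence for {self.gene_id} does not cover the "
                f"window ({len(self.seq)} nt vs {expected} nt expected)"
            )


@dataclass
class PromoterSet:
    promoters: dict[str, Promoter] = field(default_factory=dict)

    def add(self, p: Promoter) -> None:
        self.promoters[p.gene_id] = p

    def __iter__(self):
        return iter(self.promoters.values())

    def __len__(self) -> int:
        return len(self.promoters)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.promoters.values():
                fh.write(
                    f">{p.gene_id} {p.chrom}:{p.window_start}-"
                    f"{p.window_end}({p.strand}) tss={p.tss}\n{p.seq}\n"
                )

    def write_bed(self, path) -> None:
        """BED6 of promoter windows (0-based, half-open, strand col 6)."""
        with open(path, "w") as fh:
            for p in self.promoters.values():
                fh.write(
                    f"{p.chrom}\t{p.window_start - 1}\t{p.window_end}\t"
                    f"{p.gene_id}\t0\t{p.strand}\n"
                )


def _relative_position(p: Promoter, match_start_genomic: int, width: int) -> int:
    """TSS-relative, transcription-oriented coordinate of a match start."""
    if p.strand == "+":
        return match_start_genomic - p.tss
    return p.tss - (match_start_genomic + width - 1)


_CODE = np.full(256, 4, dtype=np.int8)  # N and anything else -> 4
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_promoters(
    promoters: PromoterSet,
    motifs: list[Motif],
    upstream: int = WINDOW_UP,
    downstream: int = WINDOW_DOWN,
) -> list[MotifHit]:
    """Log-odds scan of both strands of every promoter window.

    A hit is reported where the window score reaches the motif's cutoff and
    the match lies entirely within [−upstream, +downstream] in TSS-relative
    transcription-oriented coordinates.  The reverse strand is scanned with
    the reverse-complemented PWM, so hit positions refer to the forward
    match start in both cases.
    """
    hits: list[MotifHit] = []
    prepared = []
    for motif in motifs:
        lo = motif.logodds()
        lo5 = np.hstack([lo, np.zeros((lo.shape[0], 1))])  # N scores 0
        rc5 = np.hstack([lo[::-1, ::-1], np.zeros((lo.shape[0], 1))])
        prepared.append((motif, lo5, rc5, motif.score_cutoff()))
    for p in promoters:
        lo_exp, hi_exp = promoter_window(p.tss, p.strand, upstream, downstream)
        if p.window_start > lo_exp or p.window_end < hi_exp:
            raise ValueError(
                f"promoter sequence for gene {p.gene_id} does not cover the "
                f"scan window [{lo_exp}, {hi_exp}]"
            )
        bad = set(p.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"promoter for {p.gene_id}: alphabet must be ACGTN, "
                f"found {sorted(bad)}"
            )
        code = _encode(p.seq)
        for motif, lo5, rc5, cutoff in prepared:
            w = motif.length
            if len(code) < w:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(code, w)
            cols = np.arange(w)
            fwd = lo5[cols, windows].sum(axis=1)
            rev = rc5[cols, windows].sum(axis=1)
            gstarts = p.window_start + np.arange(len(fwd))
            if p.strand == "+":
                rel = gstarts - p.tss
            else:
                rel = p.tss - (gstarts + w - 1)
            inside = (rel >= -upstream) & (rel + w - 1 <= downstream)
            for strand_sym, scores in (("+", fwd), ("-", rev)):
                for idx in np.nonzero(inside & (scores >= cutoff))[0]:
                    hits.append(
                        MotifHit(
                            motif.tf_id, p.gene_id, int(rel[idx]),
                            strand_sym, float(scores[idx]),
                        )
                    )
    return hits


def hits_by_tf(hits: list[MotifHit]) -> dict[str, set[str]]:
    """TF -> set of genes with at least one window hit."""
    out: dict[str, set[str]] = {}
    for h in hits:
        out.setdefault(h.tf_id, set()).add(h.gene_id)
    return out


def write_hits_bed(
    hits: list[MotifHit], promoters: PromoterSet, path
) -> None:
    with open(path, "w") as fh:
        for h in hits:
            p = promoters.promoters[h.gene_id]
            fh.write(
                f"{p.chrom}\t{p.window_start - 1}\t{p.window_end}\t"
                f"{h.tf_id}|{h.gene_id}|rel={h.position}\t"
                f"{h.score:.3f}\t{h.strand}\n"
            )


def tf_motif_enrichment(
    deg_set: set[str],
    hits: list[MotifHit],
    universe: set[str],
    tf_ids: list[str] | None = None,
) -> EnrichmentResult:
    """Per-TF hypergeometric enrichment of motif-hit genes in a DEG set.

    The "annotation" of each TF is the set of universe genes with >= 1
    promoter hit; the query is the DEG set; BH adjustment runs across TFs.
    TFs with zero hits are reported with p = FDR = 1 so that every scanned
    TF appears in the table.
    """
    if not deg_set <= universe:
        raise ValueError(
            f"DEG genes outside the universe: {sorted(deg_set - universe)[:5]}"
        )
    per_tf = hits_by_tf(hits)
    if tf_ids is None:
        tf_ids = sorted(per_tf)
    annotation = {tf: per_tf.get(tf, set()) & universe for tf in tf_ids}
    result = enrich(deg_set, annotation, universe, min_term_size=1)
    # append zero-hit / zero-overlap TFs as p = 1 rows
    absent = [tf for tf in tf_ids if tf not in result.table.index]
    if absent:
        extra = pd.DataFrame(
            {
                "N": len(universe),
                "K": [len(annotation[tf]) for tf in absent],
                "n": len(deg_set),
                "k": 0,
                "p": 1.0,
                "FDR": 1.0,
            },
            index=pd.Index(absent, name="term"),
        )
        parts = [t for t in (result.table, extra) if len(t)]
        result = EnrichmentResult(
            table=pd.concat(parts) if len(parts) > 1 else parts[0]
        )
    return result


def coexpression_filter(
    tf_profile,
    target_profile,
    r_min: float = 0.87,
) -> tuple[bool, float]:
    """Pearson r between two mean-FPKM profiles; pass iff r > r_min (strict).

    Constant profiles have undefined correlation and fail.
    """
    a = np.asarray(tf_profile, dtype=float)
    b = np.asarray(target_profile, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("profiles must share >= 3 ordered cell types")
    if a.std() == 0 or b.std() == 0:
        return False, float("nan")  # undefined correlation
    r = float(np.corrcoef(a, b)[0, 1])
    return r > r_min, r


def build_network(
    enriched: EnrichmentResult,
    hits: list[MotifHit],
    profiles: pd.DataFrame,
    tf_gene_map: dict[str, str] | None = None,
    fdr_max: float = 0.05,
    r_min: float = 0.87,
) -> pd.DataFrame:
    """Edge list (tf_id, gene_id, r) of the predicted regulatory network.

    An edge requires all three evidence sources: TF enriched at FDR <
    ``fdr_max``, a promoter-window motif hit in the target, and TF-target
    coexpression r > ``r_min``.  ``profiles`` holds mean-FPKM rows per gene
    (TF genes included); ``tf_gene_map`` maps tf_id to its own gene_id when
    the two namespaces differ.
    """
    t = enriched.table
    enriched_tfs = set(t.index[t["FDR"] < fdr_max])
    per_tf = hits_by_tf(hits)
    rows = []
    for tf in sorted(enriched_tfs):
        tf_gene = tf_gene_map.get(tf, tf) if tf_gene_map else tf
        if tf_gene not in profiles.index:
            continue
        tf_prof = profiles.loc[tf_gene].to_numpy()
        for gene in sorted(per_tf.get(tf, set())):
            if gene not in profiles.index or gene == tf_gene:
                continue
            ok, r = coexpression_filter(
                tf_prof, profiles.loc[gene].to_numpy(), r_min
            )
            if ok:
                rows.append((tf, gene, r))
    return pd.DataFrame(rows, columns=["tf_id", "gene_id", "r"])
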