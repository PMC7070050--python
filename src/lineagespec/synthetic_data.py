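"""Synthetic study generator: counts, promoters, motifs, transcripts, truth.

Emulates the experimental design of an early-embryogenesis lineage study:
egg cell (EC), zygote at 14 h and 24 h after pollination (Zy14, Zy24), the
apical and basal daughter cells of the asymmetric zygote division (AC, BC),
and embryo proper / suspensor of the 32-cell proembryo (32E, 32S), each with
three biological replicates.  Counts are negative binomial via a
gamma-Poisson mixture with per-sample size factors; planted gene classes
(lineage-maintained profile groups, the three transcript-fate mechanisms,
embryo-activated genes, TF regulons with promoter motifs) follow canonical
expected-FPKM profiles so that every class is recoverable from its defining
rule on noiseless profiles.  The companion truth table drives recovery
metrics downstream.

Expected profiles are specified in FPKM units and converted to count means
through a nominal library size, so the class-defining FPKM thresholds used
by the fate classifier (high = 5, negligible = 1) hold by construction in
expectation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lnc_as import TranscriptModel, longest_orf_codons, revcomp, write_gtf
from .quantify import CountMatrix, write_counts
from .tf_network import Motif, Promoter, PromoterSet, promoter_window

__all__ = [
    "StudyDesign",
    "EffectConfig",
    "MotifSpec",
    "IsoformSpec",
    "TruthTable",
    "SyntheticBundle",
    "generate_counts",
    "generate_promoters_and_motifs",
    "generate_transcripts",
    "generate_bundle",
]

CELL_TYPES = ("EC", "Zy14", "Zy24", "AC", "BC", "32E", "32S")
DE_CELL_TYPES = ("Zy24", "AC", "BC", "32E", "32S")

ACL_GROUPS = ("ACL_maintained_I", "ACL_maintained_II",
              "ACL_maintained_III", "ACL_maintained_IV")
BCL_GROUPS = ("BCL_maintained_I", "BCL_maintained_II", "BCL_maintained_III")
FATE_CLASSES = ("inherited_asymmetric", "de_novo", "selective_deletion")
EMB_GROUPS = ("EMB_like_I", "EMB_like_II", "EMB_like_III")


@dataclass
class StudyDesign:
    """Sampling design: which cell types, how many replicates and genes."""

    cell_types: tuple[str, ...] = CELL_TYPES
    replicates_per_type: int = 3
    n_genes: int = 2000
    n_tf: int = 8
    n_terms: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_type < 2:
            raise ValueError("replicates_per_type must be >= 2")
        if len(self.cell_types) == 0:
            raise ValueError("cell_types must be non-empty")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell_types must be unique")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class EffectConfig:
    """Planted-effect parameters of the count generator.

    ``planted_log2fc`` is the between-lineage effect of maintained-gene
    groups (ratio 2**planted_log2fc between the favored and disfavored
    lineage).  Setting it to 0 plants no expression signal at all: the truth
    table still records class membership but every profile is flat, the null
    case for calibration checks.  FPKM states: ``on_fpkm`` is the canonical
    "high" level, ``off_fpkm`` sits well below the negligible cutoff (1
    FPKM), ``deleted_fpkm`` is the post-turnover level of selectively
    deleted transcripts.
    """

    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.03
    planted_log2fc: float = 3.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    gene_length_range: tuple[int, int] = (500, 5000)
    nominal_library_size: float = 5e6
    on_fpkm: float = 150.0
    off_fpkm: float = 0.1
    deleted_fpkm: float = 0.15
    jitter_log_sd: float = 0.25
    class_sizes: dict = field(default_factory=lambda: {
        **{g: 30 for g in ACL_GROUPS},
        **{g: 30 for g in BCL_GROUPS},
        **{c: 30 for c in FATE_CLASSES},
        **{g: 20 for g in EMB_GROUPS},
    })
    targets_per_tf: int = 20

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.on_fpkm <= 0 or self.off_fpkm <= 0 or self.deleted_fpkm <= 0:
            raise ValueError("FPKM states must be positive")
        if self.nominal_library_size <= 0:
            raise ValueError("nominal_library_size must be positive")
        lo, hi = self.size_factor_range
        if not 0 < lo <= hi:
            raise ValueError("size_factor_range must be positive and ordered")


@dataclass
class MotifSpec:
    """Promoter/motif generation parameters."""

    promoter_len: int = 601
    motif_len: int = 8
    match_prob: float = 0.91
    n_decoy_tf: int = 4
    clean_background: bool = True  # re-draw background windows hitting a motif
    upstream: int = 500
    downstream: int = 100


@dataclass
class IsoformSpec:
    """Transcript-model generation parameters (AS events and lncRNAs)."""

    as_counts: dict = field(default_factory=lambda: {
        "exon_skipping": 10,
        "alt_acceptor": 8,
        "alt_donor": 8,
        "intron_retention": 8,
        "complex": 4,
    })
    lnc_counts: dict = field(default_factory=lambda: {
        "sense": 8, "antisense": 8, "intergenic": 8,
    })
    n_short: int = 4  # < 200 nt, removed by the candidate length filter
    n_single_exon_sense: int = 4  # removed by the overlap filter
    n_coding_context: int = 10  # coding genes providing sense/antisense context
    n_lineage_specific: int = 6  # per lineage, isoforms specific to AC&32E / BC&32S
    orf_codons: int = 150
    external_vote_error: float = 0.02
    allow_overlap: bool = False


# ---------------------------------------------------------------------------
# Truth table


@dataclass
class TruthTable:
    """Planted ground truth for every downstream recovery metric."""

    genes: pd.DataFrame  # index gene_id: class, favored_lineage, is_tf, emb_group
    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    motif_consensus: dict[str, str] = field(default_factory=dict)
    transcripts: pd.DataFrame | None = None

    def genes_of_class(self, prefix: str) -> set[str]:
        cls = self.genes["class"]
        return set(cls.index[cls.str.startswith(prefix)])

    @property
    def acl_maintained(self) -> set[str]:
        return self.genes_of_class("ACL_maintained")

    @property
    def bcl_maintained(self) -> set[str]:
        return self.genes_of_class("BCL_maintained")

    def fate_truth(self) -> pd.DataFrame:
        mask = self.genes["class"].isin(FATE_CLASSES)
        return self.genes.loc[mask, ["class", "favored_lineage"]].rename(
            columns={"class": "mechanism"}
        )

    def profile_groups(self, lineage: str) -> pd.Series:
        """Planted group index (1..k) of maintained genes of one lineage."""
        groups = ACL_GROUPS if lineage == "ACL" else BCL_GROUPS
        cls = self.genes["class"]
        sub = cls[cls.isin(groups)]
        return sub.map({g: i + 1 for i, g in enumerate(groups)})

    def write(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Expected-FPKM class profiles


def class_profiles(effect: EffectConfig) -> dict[str, np.ndarray]:
    """Canonical expected-FPKM profile of each planted class.

    Columns follow CELL_TYPES order (EC, Zy14, Zy24, AC, BC, 32E, 32S).
    With planted_log2fc == 0 every profile is flat (the null case).
    """
    H = effect.on_fpkm
    off = effect.off_fpkm
    dele = effect.deleted_fpkm
    if effect.planted_log2fc == 0:
        flat = np.full(7, H / 2.0)
        return {name: flat.copy() for name in
                (*ACL_GROUPS, *BCL_GROUPS, *FATE_CLASSES, *EMB_GROUPS)}
    R = 2.0 ** effect.planted_log2fc

    def acl(ec, zy14, zy24, ac, e32):
        return np.array([ec, zy14, zy24, ac, ac / R, e32, e32 / R])

    def bcl(ec, zy14, zy24, bc, s32):
        return np.array([ec, zy14, zy24, bc / R, bc, s32 / R, s32])

    prof = {
        # four ACL-maintained shapes: de novo, ramping, inherited-flat,
        # inherited-declining (the mirrored three for BCL)
        "ACL_maintained_I": acl(off, off, off, H, H),
        "ACL_maintained_II": acl(2, 4, 6, 0.75 * H, 1.5 * H),
        "ACL_maintained_III": acl(30, 35, 40, H, 0.875 * H),
        "ACL_maintained_IV": acl(50, 45, 40, 0.6 * H, 0.3 * H),
        "BCL_maintained_I": bcl(off, off, off, H, H),
        "BCL_maintained_II": bcl(30, 35, 40, H, 0.875 * H),
        "BCL_maintained_III": bcl(50, 45, 40, 0.6 * H, 0.3 * H),
        # fate mechanisms; all are AC:BC DEGs (ratio R), none are 32E:32S
        # DEGs, so they stay disjoint from the maintained intersection rule
        "inherited_asymmetric": np.array([30, 35, 40, H, H / R, off, off]),
        "de_novo": np.array([off, off, off, H, H / R, 10, 10]),
        "selective_deletion": np.array([25, 30, 40, H, dele, 8, 8]),
        # embryo-activated shapes (no AC:BC asymmetry)
        "EMB_like_I": np.array([2, 5, 15, 30, 30, 1.2 * H, 30]),
        "EMB_like_II": np.array([0.5, 1, 3, 10, 10, H, 10]),
        "EMB_like_III": np.array([0.3, 0.3, 0.5, 2, 2, H, 5]),
    }
    return prof


def _mirror(profile: np.ndarray) -> np.ndarray:
    """Swap AC<->BC and 32E<->32S columns (favored-lineage flip)."""
    out = profile.copy()
    out[[3, 4]] = out[[4, 3]]
    out[[5, 6]] = out[[6, 5]]
    return out


# ---------------------------------------------------------------------------
# Counts


def generate_counts(
    design: StudyDesign, effect: EffectConfig | None = None
) -> tuple[CountMatrix, TruthTable]:
    """Simulate the count matrix and its planted truth table.

    Counts are NB(mean * size_factor, alpha) drawn as a gamma-Poisson
    mixture; planted classes follow ``class_profiles``; remaining genes are
    flat "null" genes with log-normal baseline count means.
    """
    effect = effect or EffectConfig()
    effect.validate()
    if tuple(design.cell_types) != CELL_TYPES:
        raise ValueError(
            f"planted classes require the canonical cell types {CELL_TYPES}"
        )
    rng = np.random.default_rng([design.seed, 1])

    total_planted = sum(effect.class_sizes.values())
    if total_planted > design.n_genes:
        raise ValueError("class sizes exceed n_genes")

    gene_ids = [f"G{i:05d}" for i in range(design.n_genes)]
    lengths = rng.integers(
        effect.gene_length_range[0], effect.gene_length_range[1] + 1,
        size=design.n_genes,
    )

    # class assignment: planted classes first, the rest null
    classes = np.array(["null"] * design.n_genes, dtype=object)
    favored = np.array([""] * design.n_genes, dtype=object)
    pos = 0
    for name, size in effect.class_sizes.items():
        classes[pos : pos + size] = name
        if name.startswith("ACL") or name == "de_novo":
            favored[pos : pos + size] = "ACL"
        elif name.startswith("BCL"):
            favored[pos : pos + size] = "BCL"
        elif name in ("inherited_asymmetric", "selective_deletion"):
            half = size // 2
            favored[pos : pos + half] = "ACL"
            favored[pos + half : pos + size] = "BCL"
        pos += size

    profiles = class_profiles(effect)
    fpkm_planted = np.zeros((design.n_genes, len(CELL_TYPES)))
    jitter = np.exp(rng.normal(0.0, effect.jitter_log_sd, design.n_genes))
    baseline = np.exp(
        rng.normal(effect.baseline_log_mean, effect.baseline_log_sd,
                   design.n_genes)
    )
    is_null = classes == "null"
    for i in range(design.n_genes):
        cls = classes[i]
        if cls == "null":
            continue
        prof = profiles[cls]
        if cls in ("inherited_asymmetric", "selective_deletion") and \
                favored[i] == "BCL":
            prof = _mirror(prof)
        fpkm_planted[i, :] = prof * jitter[i]

    # FPKM-consistent library size: planted genes state their expected FPKM,
    # null genes their expected count, so the per-sample total T solves
    #   T = sum_null(baseline) + (T / 1e9) * sum_planted(fpkm * length)
    # and planted count means f * len * T / 1e9 then realize the planted
    # FPKM in expectation.  The planted share is capped to keep T finite.
    null_total = baseline[is_null].sum() if is_null.any() else (
        effect.nominal_library_size
    )
    planted_share = (fpkm_planted.max(axis=1) * lengths).sum() / 1e9
    if planted_share >= 0.5:
        raise ValueError(
            "planted FPKM mass too large relative to null background"
        )
    library = null_total / (1.0 - planted_share)
    mean_counts = fpkm_planted * (lengths * library / 1e9)[:, None]
    mean_counts[is_null, :] = baseline[is_null, None]
    fpkm_expected = fpkm_planted.copy()
    fpkm_expected[is_null, :] = (
        baseline[is_null] * 1e9 / (lengths[is_null] * library)
    )[:, None]

    if (mean_counts <= 0).any():
        raise ValueError("non-positive expected counts")

    # TF genes: drawn from each maintained group, cycling over groups
    groups_cycle = list(ACL_GROUPS) + list(BCL_GROUPS)
    tf_targets: dict[str, set[str]] = {}
    is_tf = np.zeros(design.n_genes, dtype=bool)
    gene_index = pd.Index(gene_ids)
    cls_series = pd.Series(classes, index=gene_index)
    for t in range(design.n_tf):
        group = groups_cycle[t % len(groups_cycle)]
        members = [g for g in cls_series.index[cls_series == group]
                   if not is_tf[gene_index.get_loc(g)]]
        if len(members) < effect.targets_per_tf + 1:
            raise ValueError(
                f"group {group} too small for a TF regulon of "
                f"{effect.targets_per_tf} targets"
            )
        tf_gene = members[0]
        is_tf[gene_index.get_loc(tf_gene)] = True
        pool = [g for g in members[1:] if g not in tf_targets.get(tf_gene, ())]
        chosen = rng.choice(len(pool), size=effect.targets_per_tf,
                            replace=False)
        tf_targets[tf_gene] = {pool[j] for j in chosen}

    # samples: per-sample size factors log-uniform in the configured range
    sample_ids, cell_col, rep_col = [], [], []
    for ct in design.cell_types:
        for r in range(1, design.replicates_per_type + 1):
            sample_ids.append(f"{ct}_{r}")
            cell_col.append(ct)
            rep_col.append(r)
    lo, hi = effect.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), len(sample_ids)))

    alpha = effect.dispersion
    ct_index = {ct: j for j, ct in enumerate(CELL_TYPES)}
    counts = np.zeros((design.n_genes, len(sample_ids)), dtype=np.int64)
    for s, (sid, ct) in enumerate(zip(sample_ids, cell_col)):
        mu = mean_counts[:, ct_index[ct]] * sf[s]
        lam = rng.gamma(1.0 / alpha, alpha * mu)
        counts[:, s] = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_index, columns=sample_ids),
        lengths=pd.Series(lengths, index=gene_index, name="length"),
        samples=pd.DataFrame(
            {"cell_type": cell_col, "replicate": rep_col},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    emb = np.where(
        pd.Series(classes).str.startswith("EMB").to_numpy(), classes, ""
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "class": classes,
                "favored_lineage": favored,
                "is_tf": is_tf,
                "emb_group": emb,
                "length": lengths,
            },
            index=gene_index,
        ),
        tf_targets=tf_targets,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Promoters and motifs

_BASE_ARR = np.array(list("ACGT"))


def _random_seq(rng, n: int) -> str:
    return "".join(_BASE_ARR[rng.integers(0, 4, n)])


def generate_promoters_and_motifs(
    design: StudyDesign,
    truth: TruthTable,
    spec: MotifSpec | None = None,
) -> tuple[PromoterSet, list[Motif]]:
    """Promoter windows for every gene plus PWMs for planted and decoy TFs.

    Each planted TF's consensus is embedded exactly once inside the
    −500..+100 window of each of its targets (in transcription orientation).
    With ``clean_background`` the remaining sequence is re-drawn until it
    contains no motif consensus on either strand, so planted hits are the
    only hits — the exact-recovery regime.
    """
    spec = spec or MotifSpec()
    window_len = spec.upstream + spec.downstream + 1
    if spec.promoter_len < window_len:
        raise ValueError(
            f"promoter length must be >= {window_len} nt to cover the "
            f"-{spec.upstream}..+{spec.downstream} window"
        )
    if spec.motif_len > window_len:
        raise ValueError("motif longer than the promoter window")
    rng = np.random.default_rng([design.seed, 2])

    # distinct consensus per TF (planted TFs then decoys)
    tf_ids = sorted(truth.tf_targets) + [
        f"TFdecoy{i + 1}" for i in range(spec.n_decoy_tf)
    ]
    consensi: dict[str, str] = {}
    seen: set[str] = set()
    for tf in tf_ids:
        while True:
            cons = _random_seq(rng, spec.motif_len)
            if cons not in seen and revcomp(cons) not in seen:
                seen.add(cons)
                consensi[tf] = cons
                break
    motifs = [
        Motif.from_consensus(tf, cons, spec.match_prob)
        for tf, cons in consensi.items()
    ]
    truth.motif_consensus = dict(consensi)
    forbidden = [c for c in consensi.values()] + [
        revcomp(c) for c in consensi.values()
    ]

    forbidden = sorted(set(forbidden))

    targets_of: dict[str, list[str]] = {}
    for tf, targets in truth.tf_targets.items():
        for g in targets:
            targets_of.setdefault(g, []).append(tf)

    def build_seq(length: int, tfs: list[str], strand: str, tss: int,
                  ws: int) -> str:
        """Background with each TF consensus embedded once, no stray match.

        With clean_background, the finished sequence may contain a motif
        consensus (either strand) only at the intended embedding offsets —
        stray matches, including those straddling an insert boundary, force
        a redraw so planted hits are the only hits.
        """
        for _attempt in range(1000):
            arr = list(_random_seq(rng, length))
            placed: list[tuple[int, str]] = []
            ok = True
            for tf in tfs:
                cons = consensi[tf]
                w = len(cons)
                for _ in range(100):
                    rel = int(rng.integers(-spec.upstream,
                                           spec.downstream - w + 2))
                    off = (tss + rel if strand == "+"
                           else tss - rel - w + 1) - ws
                    if all(off + w <= o or off >= o + len(ins)
                           for o, ins in placed):
                        break
                else:
                    ok = False
                    break
                insert = cons if strand == "+" else revcomp(cons)
                placed.append((off, insert))
            if not ok:
                continue
            for off, ins in placed:
                arr[off : off + len(ins)] = list(ins)
            seq = "".join(arr)
            if not spec.clean_background:
                return seq
            intended = {
                (off, f) for off, ins in placed
                for f in (ins, revcomp(ins))
            }
            clean = True
            for f in forbidden:
                start = seq.find(f)
                while start != -1 and clean:
                    if (start, f) not in intended:
                        clean = False
                    start = seq.find(f, start + 1)
                if not clean:
                    break
            if clean:
                return seq
        raise RuntimeError("could not build a clean promoter sequence")

    promoters = PromoterSet()
    spacing = 5000
    genes_per_chrom = 400
    for i, gene in enumerate(truth.genes.index):
        chrom = f"chr{i // genes_per_chrom + 1}"
        tss = 1000 + spacing * (i % genes_per_chrom)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        ws, we = promoter_window(tss, strand, spec.upstream, spec.downstream)
        seq = build_seq(we - ws + 1, sorted(targets_of.get(gene, [])),
                        strand, tss, ws)
        promoters.add(
            Promoter(
                gene_id=gene, chrom=chrom, tss=tss, strand=strand,
                window_start=ws, window_end=we, seq=seq,
            )
        )
    return promoters, motifs


# ---------------------------------------------------------------------------
# Annotation map


def generate_annotation(design: StudyDesign, truth: TruthTable) -> dict[str, set[str]]:
    """Gene -> term map with one planted enriched term per lineage."""
    rng = np.random.default_rng([design.seed, 3])
    genes = list(truth.genes.index)
    annotation: dict[str, set[str]] = {}
    for lineage, members in (
        ("TERM_ACL", sorted(truth.acl_maintained)),
        ("TERM_BCL", sorted(truth.bcl_maintained)),
    ):
        take = min(len(members), 60)
        chosen = [members[j] for j in
                  rng.choice(len(members), size=take, replace=False)]
        extra = [genes[j] for j in rng.choice(len(genes), size=15,
                                              replace=False)]
        annotation[lineage] = set(chosen) | set(extra)
    for t in range(design.n_terms):
        size = int(rng.integers(15, 40))
        idx = rng.choice(len(genes), size=size, replace=False)
        annotation[f"TERM{t + 1:03d}"] = {genes[j] for j in idx}
    return annotation


def write_annotation(annotation: dict[str, set[str]], path) -> None:
    rows = [
        (g, term) for term in sorted(annotation)
        for g in sorted(annotation[term])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Transcripts: AS events, lncRNAs, sequences

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_CODON_WEIGHTS = np.array(
    [math.exp(sum(ch in "GC" for ch in c)) for c in _SENSE_CODONS]
)
_CODON_WEIGHTS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()


def _coding_seq(rng, n_codons: int, utr: int = 50) -> str:
    """UTR + ATG + biased sense codons + stop + UTR."""
    body = "".join(
        _SENSE_CODONS[j]
        for j in rng.choice(len(_SENSE_CODONS), size=n_codons,
                            p=_CODON_WEIGHTS)
    )
    return _random_seq(rng, utr) + "ATG" + body + "TAA" + _random_seq(rng, utr)


def _noncoding_seq(rng, n: int, max_orf: int = 100) -> str:
    while True:
        seq = _random_seq(rng, n)
        if longest_orf_codons(seq) < max_orf:
            return seq


def _as_chains(kind: str, s: int, strand: str):
    """Two exon chains differing by exactly one event of the given type.

    Donor/acceptor constructions are mirrored on the − strand so that the
    planted type is defined in transcription orientation.
    """
    a = [(s, s + 199), (s + 400, s + 599), (s + 800, s + 999)]
    if kind == "exon_skipping":
        b = [(s, s + 199), (s + 800, s + 999)]
    elif kind == "intron_retention":
        b = [(s, s + 599), (s + 800, s + 999)]
    elif kind in ("alt_donor", "alt_acceptor"):
        genomic_left = (kind == "alt_donor") == (strand == "+")
        if genomic_left:  # vary the intron's genomic-left boundary
            b = [(s, s + 249), (s + 400, s + 599), (s + 800, s + 999)]
        else:
            b = [(s, s + 199), (s + 350, s + 599), (s + 800, s + 999)]
    elif kind == "complex":
        b = [(s, s + 149), (s + 330, s + 599), (s + 800, s + 999)]
    else:
        raise ValueError(f"unknown AS type {kind!r}")
    return a, b


@dataclass
class TranscriptBundle:
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    fpkm: pd.DataFrame  # transcript x cell type expected FPKM
    truth: pd.DataFrame  # per transcript: coding, context, as_type, lineage
    hexamer_tables: tuple[np.ndarray, np.ndarray]
    external_votes: pd.DataFrame


def generate_transcripts(
    design: StudyDesign, spec: IsoformSpec | None = None
) -> TranscriptBundle:
    """Transcript models with planted AS events and lncRNA contexts.

    Coding context genes live on chrC; AS genes (two isoforms each, one
    planted event of a known type) on chrA; lncRNA candidates overlap the
    coding genes (sense/antisense) or sit in gaps (intergenic).  Transcript
    sequences are generated per transcript: coding transcripts carry a long
    biased-codon ORF, noncoding ones are rejection-sampled to have no ORF of
    >= 100 codons.  A synthetic external-votes table (two stand-in
    coding-potential tools derived from the planted truth with a small error
    rate) complements the three built-in scorers to reach the 5-vote rule.
    """
    spec = spec or IsoformSpec()
    rng = np.random.default_rng([design.seed, 4])
    transcripts: list[TranscriptModel] = []
    seqs: dict[str, str] = {}
    truth_rows = []

    def add(t: TranscriptModel, seq: str, coding: bool, context: str = "",
            as_type: str = "", lineage: str = "") -> None:
        transcripts.append(t)
        seqs[t.transcript_id] = seq
        truth_rows.append(
            (t.transcript_id, t.gene_id, coding, context, as_type, lineage,
             t.length)
        )

    # coding context genes on chrC: 3 exons, + / - strands alternating
    coding_models: list[TranscriptModel] = []
    for i in range(spec.n_coding_context):
        s = 1000 + i * 10000
        strand = "+" if i % 2 == 0 else "-"
        exons = [(s, s + 399), (s + 700, s + 1099), (s + 1400, s + 1799)]
        t = TranscriptModel(
            transcript_id=f"CODE{i:03d}.1", gene_id=f"CODE{i:03d}",
            chrom="chrC", strand=strand, exons=exons, biotype="coding",
        )
        coding_models.append(t)
        add(t, _coding_seq(rng, spec.orf_codons), coding=True)

    # AS genes on chrA: two isoforms, one planted event each
    as_index = 0
    for kind, count in spec.as_counts.items():
        for _ in range(count):
            s = 1000 + as_index * 4000
            strand = "+" if as_index % 2 == 0 else "-"
            chain_a, chain_b = _as_chains(kind, s, strand)
            gid = f"ASG{as_index:03d}"
            iso_a = TranscriptModel(f"{gid}.1", gid, "chrA", strand, chain_a,
                                    "coding")
            iso_b = TranscriptModel(f"{gid}.2", gid, "chrA", strand, chain_b,
                                    "coding")
            add(iso_a, _coding_seq(rng, spec.orf_codons), coding=True,
                as_type=kind)
            add(iso_b, _coding_seq(rng, spec.orf_codons), coding=True,
                as_type=kind)
            as_index += 1

    # lineage-specific minor isoforms: which AS isoforms are expressed where
    # (decided below through the FPKM table)
    minor_ids = [t.transcript_id for t in transcripts
                 if t.transcript_id.endswith(".2") and t.chrom == "chrA"]
    n_spec = min(spec.n_lineage_specific, len(minor_ids) // 2)
    acl_specific = minor_ids[:n_spec]
    bcl_specific = minor_ids[n_spec : 2 * n_spec]

    # lncRNA candidates
    lnc_index = 0
    for context, count in spec.lnc_counts.items():
        for _ in range(count):
            tid = f"LNC{lnc_index:03d}"
            n = int(rng.integers(300, 1500))
            if context == "intergenic":
                s = 200_000 + lnc_index * 3000
                exons = [(s, s + n // 2), (s + n // 2 + 500,
                                           s + n // 2 + 500 + (n - n // 2) - 1)]
                strand = "+" if lnc_index % 2 == 0 else "-"
            else:
                host = coding_models[lnc_index % len(coding_models)]
                strand = host.strand if context == "sense" else (
                    "+" if host.strand == "-" else "-"
                )
                h0 = host.exons[0][0]
                exons = [(h0, h0 + n // 2),
                         (h0 + n // 2 + 400, h0 + n // 2 + 400 + (n - n // 2) - 1)]
            t = TranscriptModel(tid + ".1", tid, "chrC" if context != "intergenic"
                                else "chrL", strand, exons, "candidate")
            add(t, _noncoding_seq(rng, t.length if t.length < 2000 else 1500),
                coding=False, context=context)
            lnc_index += 1

    # filter fodder: short intergenic and single-exon sense-overlapping
    for i in range(spec.n_short):
        s = 400_000 + i * 1000
        t = TranscriptModel(f"SHORT{i:02d}.1", f"SHORT{i:02d}", "chrL",
                            "+", [(s, s + 149)], "candidate")
        add(t, _noncoding_seq(rng, 150), coding=False, context="intergenic")
    for i in range(spec.n_single_exon_sense):
        host = coding_models[i % len(coding_models)]
        h0 = host.exons[0][0]
        t = TranscriptModel(f"SE{i:02d}.1", f"SE{i:02d}", "chrC",
                            host.strand, [(h0, h0 + 399)], "candidate")
        add(t, _noncoding_seq(rng, 400), coding=False, context="sense")

    if not spec.allow_overlap:
        by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
        for t in transcripts:
            by_key.setdefault((t.chrom, t.strand), []).append(t)
        for (chrom, strand), models in by_key.items():
            genes = {}
            for t in models:
                genes.setdefault(t.gene_id, []).append(t)
            spans = sorted(
                (min(x.start for x in v), max(x.end for x in v), g)
                for g, v in genes.items()
            )
            for (s1, e1, g1), (s2, e2, g2) in zip(spans, spans[1:]):
                planted_pair = {g1, g2}
                if s2 <= e1 and not any(
                    g.startswith(("LNC", "SE")) for g in planted_pair
                ):
                    raise ValueError(
                        f"planted genes overlap on {chrom}{strand}: "
                        f"{g1}/{g2} (pass allow_overlap=True to permit)"
                    )

    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "gene_id", "coding", "context",
                 "as_type", "lineage_specific", "length"],
    ).set_index("transcript_id")
    truth.loc[acl_specific, "lineage_specific"] = "ACL"
    truth.loc[bcl_specific, "lineage_specific"] = "BCL"

    # expected isoform FPKM per cell type: shared isoforms everywhere,
    # lineage-specific minors only in their lineage's cells
    cts = ["AC", "BC", "32E", "32S"]
    fpkm = pd.DataFrame(5.0, index=truth.index, columns=cts)
    fpkm.loc[acl_specific, ["BC", "32S"]] = 0.1
    fpkm.loc[bcl_specific, ["AC", "32E"]] = 0.1

    # hexamer training tables from dedicated training sequences
    from .lnc_as import build_hexamer_table

    coding_train = [_coding_seq(rng, spec.orf_codons) for _ in range(40)]
    noncoding_train = [_noncoding_seq(rng, 800) for _ in range(40)]
    tables = (build_hexamer_table(coding_train),
              build_hexamer_table(noncoding_train))

    # synthetic external coding-potential votes (2 stand-in tools)
    flips = rng.random((len(truth), 2)) < spec.external_vote_error
    noncoding = ~truth["coding"].to_numpy()
    votes = pd.DataFrame(
        {
            "tool_D": noncoding ^ flips[:, 0],
            "tool_E": noncoding ^ flips[:, 1],
        },
        index=truth.index,
    )
    return TranscriptBundle(
        transcripts=transcripts, sequences=seqs, fpkm=fpkm, truth=truth,
        hexamer_tables=tables, external_votes=votes,
    )


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SyntheticBundle:
    design: StudyDesign
    counts: CountMatrix
    truth: TruthTable
    promoters: PromoterSet
    motifs: list[Motif]
    annotation: dict[str, set[str]]
    transcripts: TranscriptBundle

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        j = lambda *p: os.path.join(outdir, *p)
        write_counts(self.counts, j("counts.tsv"), j("samples.tsv"))
        self.truth.write(j("truth_genes.tsv"))
        self.promoters.write_fasta(j("promoters.fa"))
        self.promoters.write_bed(j("tss.bed"))
        with open(j("motifs.txt"), "w") as fh:
            for m in self.motifs:
                fh.write(f">{m.tf_id} {m.consensus}\n")
                for row, base in zip(m.matrix.T, "ACGT"):
                    fh.write(base + "  [" +
                             " ".join(f"{v:.4f}" for v in row) + "]\n")
        write_annotation(self.annotation, j("annotation.tsv"))
        write_gtf(self.transcripts.transcripts, j("transcripts.gtf"))
        with open(j("transcript_seqs.fa"), "w") as fh:
            for tid in sorted(self.transcripts.sequences):
                fh.write(f">{tid}\n{self.transcripts.sequences[tid]}\n")
        self.transcripts.fpkm.to_csv(j("transcript_fpkm.tsv"), sep="\t",
                                     index_label="transcript_id")
        self.transcripts.truth.to_csv(j("truth_transcripts.tsv"), sep="\t")
        self.transcripts.external_votes.astype(int).to_csv(
            j("external_votes.tsv"), sep="\t", index_label="transcript_id"
        )
        tf_rows = [(tf, g) for tf in sorted(self.truth.tf_targets)
                   for g in sorted(self.truth.tf_targets[tf])]
        pd.DataFrame(tf_rows, columns=["tf_id", "gene_id"]).to_csv(
            j("truth_tf_targets.tsv"), sep="\t", index=False
        )
        with open(j("design.json"), "w") as fh:
            json.dump(asdict(self.design), fh, indent=2, default=str)


def generate_bundle(
    design: StudyDesign,
    effect: EffectConfig | None = None,
    motif_spec: MotifSpec | None = None,
    isoform_spec: IsoformSpec | None = None,
) -> SyntheticBundle:
    """Generate the full synthetic study (counts, promoters, transcripts)."""
    cm, truth = generate_counts(design, effect)
    promoters, motifs = generate_promoters_and_motifs(design, truth, motif_spec)
    annotation = generate_annotation(design, truth)
    tb = generate_transcripts(design, isoform_spec)
    truth.transcripts = tb.truth
    return SyntheticBundle(
        design=design, counts=cm, truth=truth, promoters=promoters,
        motifs=motifs, annotation=annotation, transcripts=tb,
    )
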