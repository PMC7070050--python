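"""End-to-end orchestration: simulate -> quantify -> DE -> structure ->
lineage classes -> enrichment -> TF network -> lncRNA/AS, with a summary
JSON of set sizes, thresholds, and (when planted truth is available)
recovery metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import de_test, enrichment, global_structure, lineage_classes
from . import lnc_as, quantify, synthetic_data, tf_network

logger = logging.getLogger("lineagespec")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

CONTRASTS = ("AC:Zy24", "BC:Zy24", "32E:AC", "32S:BC", "AC:BC", "32E:32S")


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run.

    Either ``counts_tsv``/``samples_tsv`` point at real inputs, or
    ``synthetic`` is true and the study is generated from ``seed`` with the
    design/effect parameters below.
    """

    outdir: str = "lineagespec_out"
    synthetic: bool = True
    seed: int = 0
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    n_genes: int = 2000
    n_tf: int = 8
    n_terms: int = 30
    replicates: int = 3
    dispersion: float = 0.03
    planted_log2fc: float = 3.0
    fc_min: float = 2.0
    fdr_max: float = 0.01
    expressed_fpkm: float = 1.0
    expressed_strict: bool = False
    fate_high: float = 5.0
    fate_negligible: float = 1.0
    r_min: float = 0.87
    tf_fdr_max: float = 0.05
    n_scorers: int = 5
    min_votes: int = 4
    window_upstream: int = 500
    window_downstream: int = 100
    contrasts: tuple[str, ...] = CONTRASTS
    profile_k: dict = field(default_factory=lambda: {"ACL": 4, "BCL": 3,
                                                     "EMB": 3})

    def validate(self) -> None:
        if not self.synthetic and (
            self.counts_tsv is None or self.samples_tsv is None
        ):
            raise ValueError(
                "config needs counts_tsv and samples_tsv when synthetic "
                "generation is disabled"
            )
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        for name in ("fdr_max", "tf_fdr_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [-1, 1]")
        if not 1 <= self.min_votes <= self.n_scorers:
            raise ValueError("min_votes must lie in [1, n_scorers]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "contrasts" in d:
            d["contrasts"] = tuple(d["contrasts"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path, "rb").read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        import tomllib

        return cls.from_dict(tomllib.loads(text.decode()))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the summary report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    j = lambda *p: os.path.join(config.outdir, *p)
    config.save(j("config.json"))
    summary: dict = {"thresholds": config.to_dict()}

    # ----- synthetic_data ---------------------------------------------
    bundle = None
    if config.synthetic:
        logger.info("stage synthetic_data: generating bundle")
        design = synthetic_data.StudyDesign(
            n_genes=config.n_genes, n_tf=config.n_tf, n_terms=config.n_terms,
            replicates_per_type=config.replicates, seed=config.seed,
        )
        effect = synthetic_data.EffectConfig(
            dispersion=config.dispersion,
            planted_log2fc=config.planted_log2fc,
        )
        bundle = synthetic_data.generate_bundle(design, effect)
        bundle.write(j("bundle"))
        cm = bundle.counts
    else:
        logger.info("stage quantify: reading %s", config.counts_tsv)
        cm = quantify.read_counts(config.counts_tsv, config.samples_tsv)

    # ----- quantify ----------------------------------------------------
    logger.info("stage quantify: FPKM + size factors")
    em = quantify.compute_fpkm(cm)
    sf = quantify.size_factors(cm)
    em.fpkm.to_csv(j("fpkm.tsv"), sep="\t", index_label="gene_id")
    sf.to_csv(j("size_factors.tsv"), sep="\t", index_label="sample_id")
    cell_types = list(dict.fromkeys(cm.samples["cell_type"]))
    de_types = [ct for ct in synthetic_data.DE_CELL_TYPES if ct in cell_types]
    expressed_union: set[str] = set()
    for ct in de_types or cell_types:
        expressed_union |= quantify.expressed_genes(
            em, ct, config.expressed_fpkm, config.expressed_strict
        )
    summary["expressed_union"] = len(expressed_union)

    # ----- de_test -----------------------------------------------------
    calls: dict[str, tuple[set[str], set[str]]] = {}
    for contrast in config.contrasts:
        a, b = contrast.split(":")
        if a not in cell_types or b not in cell_types:
            raise ValueError(f"contrast {contrast} references unknown groups")
        logger.info("stage de_test: %s", contrast)
        disp = de_test.estimate_dispersion(cm, [a, b], sf)
        res = de_test.nb_wald_test(cm, a, b, disp, sf)
        table = de_test.annotate_calls(res, config.fc_min, config.fdr_max)
        table.to_csv(j(f"de_{a}_vs_{b}.tsv"), sep="\t",
                     index_label="gene_id")
        calls[contrast] = de_test.call_degs(res, config.fc_min,
                                            config.fdr_max)
    summary["deg_counts"] = {
        c: {"up": len(u), "down": len(d)} for c, (u, d) in calls.items()
    }

    # ----- global_structure -------------------------------------------
    logger.info("stage global_structure")
    struct_samples = [
        s for s in cm.sample_ids
        if cm.samples.at[s, "cell_type"] in (de_types or cell_types)
    ]
    genes_for_structure = sorted(expressed_union) or list(cm.gene_ids)
    em_struct = quantify.ExpressionMatrix(
        fpkm=em.fpkm.loc[genes_for_structure, struct_samples],
        samples=em.samples.loc[struct_samples],
    )
    k = len(de_types or cell_types)
    struct = global_structure.sample_structure(em_struct, k)
    struct.correlation.to_csv(j("correlation.tsv"), sep="\t")
    struct.pca_coords.to_csv(j("pca.tsv"), sep="\t", index_label="sample_id")
    with open(j("dendrogram.nwk"), "w") as fh:
        fh.write(global_structure.dendrogram_newick(
            struct.linkage, list(struct.correlation.index)) + "\n")
    within = []
    for ct in de_types or cell_types:
        ids = [s for s in struct_samples
               if cm.samples.at[s, "cell_type"] == ct]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                within.append(struct.correlation.at[ids[x], ids[y]])
    summary["min_within_celltype_r"] = round(float(np.min(within)), 4)
    true_ct = [cm.samples.at[s, "cell_type"] for s in struct_samples]
    summary["uhc_ari"] = round(float(
        adjusted_rand_score(true_ct, struct.labels.loc[struct_samples])
    ), 4)

    # ----- lineage_classes --------------------------------------------
    logger.info("stage lineage_classes")
    sets = lineage_classes.lineage_maintained(
        calls["AC:BC"], calls["32E:32S"]
    )
    fate = lineage_classes.classify_transcript_fate(
        em, calls["AC:BC"],
        lineage_classes.FateThresholds(config.fate_high,
                                       config.fate_negligible),
    )
    fate.to_csv(j("fate_labels.tsv"), sep="\t", index_label="gene_id")
    pd.Series(sorted(sets.acl_maintained)).to_csv(
        j("acl_maintained.tsv"), sep="\t", index=False, header=["gene_id"])
    pd.Series(sorted(sets.bcl_maintained)).to_csv(
        j("bcl_maintained.tsv"), sep="\t", index=False, header=["gene_id"])
    summary["acl_maintained"] = len(sets.acl_maintained)
    summary["bcl_maintained"] = len(sets.bcl_maintained)
    profile_groups = {}
    for lineage, genes in (("ACL", sets.acl_maintained),
                           ("BCL", sets.bcl_maintained)):
        if len(genes) >= config.profile_k[lineage]:
            profile_groups[lineage] = lineage_classes.cluster_profiles(
                em, genes, config.profile_k[lineage]
            )
            profile_groups[lineage].to_csv(
                j(f"profile_groups_{lineage}.tsv"), sep="\t")

    # ----- enrichment --------------------------------------------------
    logger.info("stage enrichment")
    if bundle is not None:
        annotation = bundle.annotation
    else:
        annotation = {}
    universe = expressed_union | sets.acl_maintained | sets.bcl_maintained
    if annotation:
        for lineage, genes in (("ACL", sets.acl_maintained),
                               ("BCL", sets.bcl_maintained)):
            result = enrichment.enrich(genes, annotation, universe)
            result.table.to_csv(j(f"enrichment_{lineage}.tsv"), sep="\t")
            summary[f"top_term_{lineage}"] = (
                str(result.table.index[0]) if len(result.table) else None
            )

    # ----- tf_network --------------------------------------------------
    edges = pd.DataFrame(columns=["tf_id", "gene_id", "r"])
    if bundle is not None:
        logger.info("stage tf_network: scanning %d promoters",
                    len(bundle.promoters))
        hits = tf_network.scan_promoters(
            bundle.promoters, bundle.motifs,
            config.window_upstream, config.window_downstream,
        )
        tf_network.write_hits_bed(hits, bundle.promoters, j("motif_hits.bed"))
        tf_ids = [m.tf_id for m in bundle.motifs]
        profiles = em.group_means()
        enriched_tables = []
        for direction, deg in (("up", calls["AC:BC"][0]),
                               ("down", calls["AC:BC"][1])):
            enr = tf_network.tf_motif_enrichment(
                deg & universe, hits, universe, tf_ids
            )
            enr.table.to_csv(j(f"tf_enrichment_{direction}.tsv"), sep="\t")
            net = tf_network.build_network(
                enr, hits, profiles,
                fdr_max=config.tf_fdr_max, r_min=config.r_min,
            )
            enriched_tables.append((direction, enr, net))
        nets = [n for _, _, n in enriched_tables if len(n)]
        if nets:
            edges = pd.concat(nets, ignore_index=True).drop_duplicates()
        edges.to_csv(j("network_edges.tsv"), sep="\t", index=False)
        summary["network_edges"] = len(edges)
        summary["enriched_tfs"] = sorted(
            {tf for _, enr, _ in enriched_tables
             for tf in enr.table.index[enr.table["FDR"] < config.tf_fdr_max]}
        )

    # ----- lnc_as ------------------------------------------------------
    lnc_calls_df = None
    if bundle is not None:
        logger.info("stage lnc_as")
        tb = bundle.transcripts
        coding = [t for t in tb.transcripts if t.biotype == "coding"]
        cands = [t for t in tb.transcripts if t.biotype == "candidate"]
        kept = lnc_as.filter_candidates(cands, coding)
        rows = []
        for t in kept:
            context = lnc_as.classify_context(t, coding)
            votes = lnc_as.builtin_scorers(
                tb.sequences[t.transcript_id], tb.hexamer_tables
            )
            ordered = [votes["orf"], votes["hexamer"], votes["stop_density"]]
            ext = tb.external_votes.loc[t.transcript_id]
            ordered += [bool(ext["tool_D"]), bool(ext["tool_E"])]
            is_lnc = lnc_as.vote_lncRNA(ordered, config.n_scorers,
                                        config.min_votes)
            rows.append((t.transcript_id, context,
                         "".join("1" if v else "0" for v in ordered), is_lnc))
        lnc_calls_df = pd.DataFrame(
            rows, columns=["transcript_id", "context", "votes", "is_lncRNA"]
        ).set_index("transcript_id")
        lnc_calls_df.to_csv(j("lnc_calls.tsv"), sep="\t")
        summary["lncRNAs"] = int(lnc_calls_df["is_lncRNA"].sum())
        summary["lnc_contexts"] = (
            lnc_calls_df.loc[lnc_calls_df["is_lncRNA"], "context"]
            .value_counts().to_dict()
        )

        by_gene: dict[str, list] = {}
        for t in tb.transcripts:
            if t.chrom == "chrA":
                by_gene.setdefault(t.gene_id, []).append(t)
        events = []
        for gid, isoforms in sorted(by_gene.items()):
            events.extend(lnc_as.detect_as_events(isoforms))
        pd.DataFrame(
            [(e.gene_id, e.isoform_a, e.isoform_b, e.type,
              e.region[0], e.region[1]) for e in events],
            columns=["gene_id", "isoform_a", "isoform_b", "type",
                     "region_start", "region_end"],
        ).to_csv(j("as_events.tsv"), sep="\t", index=False)
        summary["as_events"] = (
            pd.Series([e.type for e in events]).value_counts().to_dict()
        )
        iso_sets = {
            ct: set(tb.fpkm.index[tb.fpkm[ct] >= config.expressed_fpkm])
            for ct in ("AC", "BC", "32E", "32S")
        }
        spec_sets = lnc_as.compare_across_cells(iso_sets)
        summary["isoform_sets"] = {k: len(v) for k, v in spec_sets.items()}

    # ----- recovery vs truth ------------------------------------------
    if bundle is not None:
        truth = bundle.truth
        rec = {}
        rec["acl_jaccard"] = round(
            _jaccard(sets.acl_maintained, truth.acl_maintained), 4)
        rec["bcl_jaccard"] = round(
            _jaccard(sets.bcl_maintained, truth.bcl_maintained), 4)
        ft = truth.fate_truth()
        common = ft.index.intersection(fate.index)
        rec["fate_accuracy"] = round(float(
            (fate.loc[common, "mechanism"] == ft.loc[common, "mechanism"])
            .mean()
        ), 4) if len(common) else 0.0
        rec["fate_coverage"] = round(len(common) / len(ft), 4)
        planted_edges = {
            (tf, g) for tf, ts in truth.tf_targets.items() for g in ts
        }
        got_edges = set(zip(edges["tf_id"], edges["gene_id"]))
        rec["network_precision"] = round(
            len(got_edges & planted_edges) / len(got_edges), 4
        ) if got_edges else 0.0
        rec["network_recall"] = round(
            len(got_edges & planted_edges) / len(planted_edges), 4
        ) if planted_edges else 1.0
        for lineage in profile_groups:
            pg = profile_groups[lineage]
            pt = truth.profile_groups(lineage)
            common = pg.index.intersection(pt.index)
            if len(common):
                rec[f"profile_ari_{lineage}"] = round(float(
                    adjusted_rand_score(pt.loc[common], pg.loc[common,
                                                               "group"])
                ), 4)
        if lnc_calls_df is not None:
            tt = truth.transcripts
            noncoding = set(tt.index[~tt["coding"]])
            called = set(lnc_calls_df.index[lnc_calls_df["is_lncRNA"]])
            in_play = set(lnc_calls_df.index) & noncoding
            rec["lnc_recall"] = round(
                len(called & noncoding) / len(in_play), 4
            ) if in_play else 1.0
        summary["recovery"] = rec

    with open(j("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", j("summary.json"))
    return summary
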