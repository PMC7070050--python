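import numpy as np
import pandas as pd
import pytest

from lineagespec import quantify, synthetic_data
from lineagespec.synthetic_data import (
    CELL_TYPES,
    EffectConfig,
    IsoformSpec,
    MotifSpec,
    StudyDesign,
    generate_bundle,
    generate_counts,
    generate_promoters_and_motifs,
    generate_transcripts,
)


class TestDeterminism:
    def test_counts_reproducible_by_seed(self):
        design = StudyDesign(seed=1, n_genes=600)
        cm1, t1 = generate_counts(design)
        cm2, t2 = generate_counts(design)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        assert t1.tf_targets == t2.tf_targets

    def test_bundle_serialization_byte_identical(self, tmp_path):
        design = StudyDesign(seed=3, n_genes=600)
        for sub in ("a", "b"):
            generate_bundle(design).write(tmp_path / sub)
        for name in ("counts.tsv", "promoters.fa", "transcripts.gtf",
                     "truth_genes.tsv", "motifs.txt", "external_votes.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        cm1, _ = generate_counts(StudyDesign(seed=1, n_genes=600))
        cm2, _ = generate_counts(StudyDesign(seed=2, n_genes=600))
        assert not cm1.counts.equals(cm2.counts)


class TestCountModel:
    def test_nb_moments_of_null_genes(self):
        """Empirical variance of null genes matches mu + alpha mu^2."""
        design = StudyDesign(seed=4, n_genes=5000, n_tf=0,
                             replicates_per_type=3)
        effect = EffectConfig(dispersion=0.1, class_sizes={},
                              size_factor_range=(1.0, 1.0))
        cm, truth = generate_counts(design, effect)
        # pool replicates of one cell type; all genes are null here
        cols = cm.samples_of("AC")
        x = cm.counts[cols].to_numpy(dtype=float)
        mu = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        keep = mu > 50
        alpha_hat = np.mean((v[keep] - mu[keep]) / mu[keep] ** 2)
        assert alpha_hat == pytest.approx(0.1, rel=0.1)

    def test_planted_fold_change_in_expectation(self):
        """ACL-maintained group means in AC exceed BC at least 4-fold."""
        design = StudyDesign(seed=5, n_genes=2000)
        effect = EffectConfig(dispersion=0.1)
        cm, truth = generate_counts(design, effect)
        em = quantify.compute_fpkm(cm)
        means = em.group_means(["AC", "BC"])
        acl = sorted(truth.acl_maintained)
        ratio = means.loc[acl, "AC"].mean() / means.loc[acl, "BC"].mean()
        assert ratio >= 4.0

    def test_null_effect_config_plants_no_signal(self):
        design = StudyDesign(seed=6, n_genes=600)
        cm, truth = generate_counts(design, EffectConfig(planted_log2fc=0.0))
        em = quantify.compute_fpkm(cm)
        means = em.group_means(["AC", "BC"])
        acl = sorted(truth.acl_maintained)
        lfc = np.log2(means.loc[acl, "AC"] + 0.5) - \
            np.log2(means.loc[acl, "BC"] + 0.5)
        assert np.abs(lfc.mean()) < 0.2

    def test_noiseless_profiles_recover_every_class(self):
        """The defining rule of each class holds on expected-value profiles."""
        effect = EffectConfig()
        prof = synthetic_data.class_profiles(effect)
        idx = {ct: i for i, ct in enumerate(CELL_TYPES)}
        for name in synthetic_data.ACL_GROUPS:
            p = prof[name]
            assert p[idx["AC"]] / p[idx["BC"]] >= 2
            assert p[idx["32E"]] / p[idx["32S"]] >= 2
        for name in synthetic_data.BCL_GROUPS:
            p = prof[name]
            assert p[idx["BC"]] / p[idx["AC"]] >= 2
            assert p[idx["32S"]] / p[idx["32E"]] >= 2
        p = prof["inherited_asymmetric"]
        assert p[idx["Zy24"]] >= 5 and max(p[idx["32E"]], p[idx["32S"]]) < 1
        p = prof["de_novo"]
        assert p[idx["Zy24"]] < 1 and p[idx["AC"]] >= 5
        p = prof["selective_deletion"]
        assert p[idx["Zy24"]] >= 5 and p[idx["AC"]] >= 5 and p[idx["BC"]] < 1
        # fate classes must not satisfy the 32-cell maintained rule
        for name in synthetic_data.FATE_CLASSES:
            p = prof[name]
            assert p[idx["32E"]] / p[idx["32S"]] < 2

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            StudyDesign(replicates_per_type=1)
        with pytest.raises(ValueError):
            generate_counts(StudyDesign(n_genes=600),
                            EffectConfig(dispersion=-1.0))
        with pytest.raises(ValueError):
            generate_counts(StudyDesign(n_genes=600),
                            EffectConfig(off_fpkm=0.0))
        with pytest.raises(ValueError, match="n_genes"):
            generate_counts(StudyDesign(n_genes=100))


class TestPromoters:
    def test_planted_consensus_in_every_target_window(self, default_bundle):
        from lineagespec.lnc_as import revcomp

        truth = default_bundle.truth
        for tf, targets in truth.tf_targets.items():
            cons = truth.motif_consensus[tf]
            for g in targets:
                p = default_bundle.promoters.promoters[g]
                assert cons in p.seq or revcomp(cons) in p.seq

    def test_clean_background_has_no_spurious_hits(self, default_bundle):
        from lineagespec import tf_network

        hits = tf_network.scan_promoters(default_bundle.promoters,
                                         default_bundle.motifs)
        per_tf = tf_network.hits_by_tf(hits)
        for tf, targets in default_bundle.truth.tf_targets.items():
            assert per_tf[tf] == targets
        for m in default_bundle.motifs:
            if m.tf_id.startswith("TFdecoy"):
                assert m.tf_id not in per_tf

    def test_background_hit_rate_matches_closed_form(self):
        """Without planted targets, the expected number of exact-consensus
        windows per promoter is 2 * (L - w + 1) / 4^w."""
        from lineagespec import tf_network

        design = StudyDesign(seed=7, n_genes=2000, n_tf=0)
        effect = EffectConfig(class_sizes={})
        cm, truth = generate_counts(design, effect)
        truth.tf_targets = {}
        spec = MotifSpec(clean_background=False, motif_len=6, n_decoy_tf=1)
        promoters, motifs = generate_promoters_and_motifs(design, truth, spec)
        hits = tf_network.scan_promoters(promoters, motifs)
        L, w = 601, 6
        expected = 2 * (L - w + 1) / 4 ** w * len(promoters)
        got = len(hits)
        # Poisson tolerance: 4 sigma around the closed-form expectation
        assert abs(got - expected) <= 4 * np.sqrt(expected)

    def test_motif_longer_than_window_rejected(self):
        design = StudyDesign(seed=8, n_genes=600)
        _, truth = generate_counts(design)
        with pytest.raises(ValueError):
            generate_promoters_and_motifs(design, truth,
                                          MotifSpec(motif_len=700))

    def test_short_promoter_rejected(self):
        design = StudyDesign(seed=8, n_genes=600)
        _, truth = generate_counts(design)
        with pytest.raises(ValueError, match="601"):
            generate_promoters_and_motifs(design, truth,
                                          MotifSpec(promoter_len=400))


class TestTranscripts:
    def test_planted_as_types_detected_exactly(self, default_bundle):
        from lineagespec.lnc_as import detect_as_events

        tb = default_bundle.transcripts
        by_gene = {}
        for t in tb.transcripts:
            if t.chrom == "chrA":
                by_gene.setdefault(t.gene_id, []).append(t)
        type_counts = {}
        for gid, isoforms in by_gene.items():
            events = detect_as_events(isoforms)
            assert len(events) == 1
            type_counts[events[0].type] = type_counts.get(events[0].type,
                                                          0) + 1
        assert type_counts == IsoformSpec().as_counts

    def test_planted_contexts_and_filters(self, default_bundle):
        from lineagespec.lnc_as import classify_context, filter_candidates

        tb = default_bundle.transcripts
        coding = [t for t in tb.transcripts if t.biotype == "coding"]
        cands = [t for t in tb.transcripts if t.biotype == "candidate"]
        kept = filter_candidates(cands, coding)
        kept_ids = {t.transcript_id for t in kept}
        # fodder removed, planted lncRNAs retained
        assert not any(i.startswith(("SHORT", "SE")) for i in kept_ids)
        for t in kept:
            truth_ctx = tb.truth.at[t.transcript_id, "context"]
            assert classify_context(t, coding) == truth_ctx

    def test_lineage_specific_isoforms_recovered(self, default_bundle):
        from lineagespec.lnc_as import compare_across_cells

        tb = default_bundle.transcripts
        sets = {ct: set(tb.fpkm.index[tb.fpkm[ct] >= 1.0])
                for ct in ("AC", "BC", "32E", "32S")}
        out = compare_across_cells(sets)
        truth = tb.truth
        assert out["ACL_maintained"] == set(
            truth.index[truth["lineage_specific"] == "ACL"])
        assert out["BCL_maintained"] == set(
            truth.index[truth["lineage_specific"] == "BCL"])

    def test_coding_sequences_have_long_orfs(self, default_bundle):
        from lineagespec.lnc_as import longest_orf_codons

        tb = default_bundle.transcripts
        for tid, row in tb.truth.iterrows():
            n = longest_orf_codons(tb.sequences[tid])
            if row["coding"]:
                assert n >= 100
            else:
                assert n < 100
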