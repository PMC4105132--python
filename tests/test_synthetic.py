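import numpy as np
import pytest

from charkit import (
    annotation as an,
    codon_usage as cu,
    read_qc as rq,
    seq_core as sc,
    ssr_miner as sm,
    synthetic as syn,
)
from charkit.orthology import reciprocal_best_hits
from charkit.seq_core import CharkitError


class TestGenTranscriptome:
    def test_mean_length_near_target(self):
        recs = syn.gen_transcriptome(syn.GeneratorConfig(seed=1, n_sequences=1000))
        mean = np.mean([len(r) for r in recs])
        assert abs(mean - 571) / 571 < 0.10

    def test_gc_near_target(self):
        recs = syn.gen_transcriptome(
            syn.GeneratorConfig(seed=2, n_sequences=300, gc=0.51)
        )
        stats = sc.assembly_stats(recs)
        assert abs(stats.gc_fraction - 0.51) < 0.02

    def test_same_seed_identical(self):
        cfg = syn.GeneratorConfig(seed=7, n_sequences=50)
        a = syn.gen_transcriptome(cfg)
        b = syn.gen_transcriptome(cfg)
        assert a == b

    def test_min_length_respected(self):
        recs = syn.gen_transcriptome(syn.GeneratorConfig(seed=3, n_sequences=200))
        assert min(len(r) for r in recs) >= 200

    def test_invalid_config_rejected(self):
        with pytest.raises(CharkitError):
            syn.GeneratorConfig(seed=1, gc=1.5)


class TestPlantSsrs:
    def _hosts(self, seed=11, n=5):
        return syn.gen_transcriptome(
            syn.GeneratorConfig(seed=seed, n_sequences=n, mean_length=1500.0,
                                sigma_log=0.05, min_length=1200)
        )

    def test_planted_run_found_exactly(self):
        planted, truth = syn.plant_ssrs(
            self._hosts(), [], seed=12, placements=[("unigene_00001", "AT", 6)]
        )
        host = next(r for r in planted if r.id == "unigene_00001")
        hits = sm.find_ssrs(host)
        assert len(hits) == 1
        row = truth.iloc[0]
        assert (hits[0].motif, hits[0].repeat_count) == ("AT", 6)
        assert (hits[0].start, hits[0].end) == (row.start, row.end)

    def test_below_threshold_plant_invisible(self):
        planted, _ = syn.plant_ssrs(
            self._hosts(seed=13), [], seed=14,
            placements=[("unigene_00001", "AT", 5)],
        )
        host = next(r for r in planted if r.id == "unigene_00001")
        assert sm.find_ssrs(host) == []

    def test_too_short_host_is_error(self):
        short = [sc.SequenceRecord(id="tiny", seq="ACGTACGT")]
        with pytest.raises(CharkitError):
            syn.plant_ssrs(short, [], seed=1, placements=[("tiny", "AT", 6)])

    def test_truth_round_trips_tsv(self, tmp_path):
        _, truth = syn.plant_ssrs(
            self._hosts(seed=15), [("AT", 6, 3)], seed=16
        )
        p = tmp_path / "truth.tsv"
        syn.truth_to_tsv(truth, p)
        back = syn.truth_from_tsv(p)
        assert back.equals(truth)


class TestGenCdsSet:
    def test_full_bias_gives_nc_20(self):
        recs, _ = syn.gen_cds_set(5, 500, 0.5, 1.0, seed=20)
        for r in recs:
            nc = cu.effective_number_of_codons(cu.count_codons(r.seq))
            assert nc == 20.0

    def test_unbiased_genes_sit_on_expected_curve(self):
        recs, _ = syn.gen_cds_set(100, 500, 0.5, 0.0, seed=21)
        ncs = [cu.effective_number_of_codons(cu.count_codons(r.seq)) for r in recs]
        assert abs(np.mean(ncs) - cu.expected_nc(0.5)) < 1.5

    def test_bias_sweep_monotone_decreasing(self):
        means = []
        for b in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            recs, _ = syn.gen_cds_set(30, 400, 0.5, b, seed=22)
            means.append(
                np.mean(
                    [cu.effective_number_of_codons(cu.count_codons(r.seq)) for r in recs]
                )
            )
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_gc3_tracks_target(self):
        recs, _ = syn.gen_cds_set(50, 500, 0.7, 0.0, seed=23)
        assert abs(np.mean([cu.gc3(r.seq) for r in recs]) - 0.7) < 0.03

    def test_determinism_and_truth_fields(self):
        a, ta = syn.gen_cds_set(10, 100, 0.6, (0.1, 0.9), seed=24)
        b, tb = syn.gen_cds_set(10, 100, 0.6, (0.1, 0.9), seed=24)
        assert a == b and ta.equals(tb)
        assert set(ta.columns) >= {"id", "bias_strength", "gc3_target", "n_codons"}

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(CharkitError):
            syn.gen_cds_set(5, 100, 1.2, 0.0, seed=1)
        with pytest.raises(CharkitError):
            syn.gen_cds_set(5, 100, 0.5, (0.5, 1.5), seed=1)


class TestGenReads:
    def _transcripts(self):
        return syn.gen_transcriptome(syn.GeneratorConfig(seed=30, n_sequences=40))

    def test_cleaning_removes_exactly_the_labelled_set(self):
        r1, r2, truth = syn.gen_reads(
            self._transcripts(), n_pairs=400, fail_n_fraction=0.05,
            fail_lowq_fraction=0.05, seed=31,
        )
        k1, k2, _ = rq.clean_read_pairs(r1, r2)
        kept_pairs = {r.id.rsplit("/", 1)[0] for r in k1}
        expected = set(truth[truth.label == "pass"].pair_id)
        assert kept_pairs == expected

    def test_zero_noise_keeps_everything(self):
        r1, r2, truth = syn.gen_reads(
            self._transcripts(), n_pairs=100, fail_n_fraction=0.0,
            fail_lowq_fraction=0.0, seed=32,
        )
        k1, k2, rep = rq.clean_read_pairs(r1, r2)
        assert rep.n_clean == 200 and (truth.label == "pass").all()

    def test_same_seed_identical(self):
        a = syn.gen_reads(self._transcripts(), n_pairs=50, seed=33)
        b = syn.gen_reads(self._transcripts(), n_pairs=50, seed=33)
        assert a[0] == b[0] and a[1] == b[1] and a[2].equals(b[2])

    def test_read_geometry(self):
        r1, r2, _ = syn.gen_reads(self._transcripts(), n_pairs=20, seed=34)
        assert all(len(r) == 90 for r in r1 + r2)


class TestGenOrthologTables:
    def test_zero_noise_recovers_all_planted_pairs(self):
        ab, ba, truth = syn.gen_ortholog_tables(50, 60, 25, score_noise=0.0, seed=40)
        pairs = {(p.id_a, p.id_b) for p in reciprocal_best_hits(ab, ba)}
        assert pairs == set(zip(truth.id_a, truth.id_b))

    def test_decoys_only_gives_no_pairs(self):
        ab, ba, _ = syn.gen_ortholog_tables(
            40, 40, 0, decoy_rate=1.0, seed=41
        )
        assert ab and ba
        assert reciprocal_best_hits(ab, ba) == []

    def test_noise_degrades_recall_monotonically_on_average(self):
        recalls = []
        for noise in (0.0, 3.0):
            vals = []
            for seed in range(5):
                ab, ba, truth = syn.gen_ortholog_tables(
                    40, 40, 20, score_noise=noise, decoy_rate=0.8, seed=50 + seed
                )
                pairs = {(p.id_a, p.id_b) for p in reciprocal_best_hits(ab, ba)}
                vals.append(len(pairs & set(zip(truth.id_a, truth.id_b))) / 20)
            recalls.append(np.mean(vals))
        assert recalls[0] == 1.0 and recalls[1] < 1.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(CharkitError):
            syn.gen_ortholog_tables(5, 5, 10, seed=1)


class TestGenExpression:
    def test_same_seed_identical(self):
        _, truth = syn.gen_cds_set(30, 200, 0.5, (0.0, 0.8), seed=60)
        a = syn.gen_expression(truth, coupling=0.5, seed=61)
        b = syn.gen_expression(truth, coupling=0.5, seed=61)
        assert a == b

    def test_coupling_links_bias_and_expression(self):
        _, truth = syn.gen_cds_set(500, 200, 0.5, (0.0, 0.9), seed=62)
        expr = syn.gen_expression(truth, coupling=0.8, seed=63)
        by_id = {e.id: e for e in expr}
        xs, ys = [], []
        for row in truth.itertuples():
            e = by_id[row.id]
            if e.log10_fpkm is not None:
                xs.append(row.bias_strength)
                ys.append(e.log10_fpkm)
        r, p = cu.pearson(xs, ys)
        assert r > 0 and p < 0.01

    def test_zero_coupling_independent(self):
        _, truth = syn.gen_cds_set(500, 200, 0.5, (0.0, 0.9), seed=64)
        expr = syn.gen_expression(truth, coupling=0.0, seed=65)
        by_id = {e.id: e for e in expr}
        xs = truth.bias_strength.to_list()
        ys = [by_id[i].log10_fpkm or 0.0 for i in truth.id]
        r, _ = cu.pearson(xs, ys)
        assert abs(r) < 0.15


class TestStudyBundle:
    def test_bundle_artifacts_parse_and_agree_with_truth(self):
        bundle = syn.gen_study_bundle(seed=77)
        # annotation recovers every planted CDS exactly
        anns = an.annotate(bundle.transcripts, bundle.per_db_hits)
        by_gene = bundle.cds_truth.set_index("transcript_id")
        genes = {g.id: g for g in bundle.cds_records}
        for tid, row in by_gene.iterrows():
            if tid in anns and anns[tid].source_db != "fallback":
                assert anns[tid].cds_seq == genes[row["id"]].seq
                assert anns[tid].orientation == row["orientation"]
        # reads: survivors equal the labelled pass set
        k1, _, _ = rq.clean_read_pairs(bundle.reads1, bundle.reads2)
        kept = {r.id.rsplit("/", 1)[0] for r in k1}
        assert kept == set(bundle.read_truth[bundle.read_truth.label == "pass"].pair_id)
        # SSR counts match the planted truth
        hits, summary = sm.ssr_scan(bundle.ssr_hosts, min_seq_nt=1000)
        assert summary.n_ssrs == len(bundle.ssr_truth)
        assert summary.n_sequences_with_ssr == bundle.ssr_truth.seq_id.nunique()
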