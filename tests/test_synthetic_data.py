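"""Calibrated synthetic cohorts and rendered token streams."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from pronocase import annotation as A
from pronocase import corpus_io as C
from pronocase import features as F
from pronocase import synthetic_data as S


class TestGenerateCohort:
    def test_suicidal_count_within_binomial_bounds(self):
        cfg = S.GeneratorConfig(seed=2)
        _, labels = S.generate_cohort(cfg)
        n_sui = sum(lab.suicidal_ideation for lab in labels)
        dist = sps.binom(cfg.n_participants, cfg.prevalence)
        lo, hi = dist.ppf(0.005), dist.ppf(0.995)
        assert lo <= n_sui <= hi

    def test_zero_prevalence_all_non_suicidal(self):
        cfg = S.GeneratorConfig(prevalence=0.0, seed=0)
        _, labels = S.generate_cohort(cfg)
        assert not any(lab.suicidal_ideation for lab in labels)

    def test_deterministic_given_seed(self):
        cfg = S.GeneratorConfig(seed=123)
        a = S.generate_cohort(cfg)
        b = S.generate_cohort(cfg)
        assert a == b

    def test_labels_rederivable_from_metadata(self):
        """The intended labels are exactly recoverable from the written
        ratings through the label-derivation rule."""
        records, labels = S.generate_cohort(S.GeneratorConfig(seed=5))
        for record, intended in zip(records, labels):
            assert C.derive_labels(record) == intended

    def test_ages_within_band(self):
        records, _ = S.generate_cohort(S.GeneratorConfig(seed=1))
        assert all(18 <= r.age <= 65 for r in records)

    @pytest.mark.parametrize("kwargs", [
        {"prevalence": 1.5}, {"n_participants": 1},
        {"tokens_min": 0}, {"tokens_min": 100, "tokens_max": 50},
        {"pro_drop": -0.1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(S.GenerationError):
            S.GeneratorConfig(**kwargs)


class TestGenerateTranscript:
    TARGETS = {k: v[2] for k, v in S.GROUP_RATE_DEFAULTS.items()}

    def test_rates_converge_at_large_n(self):
        """At 50k tokens, extracted rates land within 3 multinomial standard
        errors of their targets."""
        n_tokens = 50_000
        utts = S.generate_transcript(self.TARGETS, n_tokens, seed=1)
        fv = F.extract_features(utts)
        for name, target in self.TARGETS.items():
            p = target / 100.0
            se_pct = 100.0 * np.sqrt(p * (1 - p) / fv.token_total)
            assert abs(getattr(fv, name) - target) <= max(3 * se_pct, 1e-9), name

    def test_zero_objective_rate_yields_zero_extraction(self):
        targets = dict(self.TARGETS, objective_fpsp=0.0)
        utts = S.generate_transcript(targets, 5_000, seed=2)
        fv = F.extract_features(utts)
        assert fv.objective_fpsp == 0.0

    def test_deterministic_given_seed(self):
        a = S.generate_transcript(self.TARGETS, 2_000, seed=9)
        b = S.generate_transcript(self.TARGETS, 2_000, seed=9)
        assert a == b

    def test_all_parses_valid(self):
        utts = S.generate_transcript(self.TARGETS, 1_000, seed=3)
        assert all(A.validate_parse(u) for u in utts)
        assert sum(len(u) for u in utts) >= 1_000

    def test_unreachable_verb_rate_rejected(self):
        # subjective templates alone embed more verbs than the verb target
        targets = {"subjective_fpsp": 30.0, "verb": 1.0}
        with pytest.raises(S.GenerationError, match="verb"):
            S.generate_transcript(targets, 1_000, seed=0)

    def test_overfull_rates_rejected(self):
        targets = {"interjection": 80.0, "verb": 40.0}
        with pytest.raises(S.GenerationError):
            S.generate_transcript(targets, 1_000, seed=0)

    def test_pro_drop_lowers_realized_subject_count_but_not_rate(self):
        """Dropped subjects are compensated in the template mix, so the
        subjective rate still hits its target."""
        targets = {"subjective_fpsp": 2.0, "verb": 10.0}
        utts = S.generate_transcript(targets, 40_000, seed=4, pro_drop=0.5)
        fv = F.extract_features(utts)
        se = 100 * np.sqrt(0.02 * 0.98 / fv.token_total)
        assert abs(fv.subjective_fpsp - 2.0) <= 3 * se


class TestGenerateDataset:
    def test_layout_and_manifest(self, small_dataset):
        assert (small_dataset / "metadata.csv").exists()
        assert (small_dataset / "true_rates.csv").exists()
        manifest = json.loads((small_dataset / "manifest.json").read_text())
        assert manifest["seed"] == 7
        transcripts = sorted((small_dataset / "corpus").glob("*.jsonl"))
        assert len(transcripts) == 12

    def test_extraction_recovers_configured_rates(self, small_dataset):
        """Full pipeline self-consistency: per-participant extracted counts
        sit within 3 multinomial SEs of the generator's configured targets
        (count scale, with a +3 allowance where the expected count is so
        small that the normal approximation is skewed)."""
        import pandas as pd

        truth = pd.read_csv(small_dataset / "true_rates.csv",
                            index_col="participant_id")
        records = C.read_metadata(small_dataset / "metadata.csv")
        ann = A.TemplateAnnotator()
        for record in records:
            turns = C.read_transcript(
                small_dataset / "corpus" / f"{record.participant_id}.jsonl")
            utts = []
            for text in C.participant_text(turns):
                utts.extend(A.annotate(text, ann))
            fv = F.extract_features(utts)
            n = fv.token_total
            for name in S.GROUP_RATE_DEFAULTS:
                p = truth.loc[record.participant_id, name] / 100.0
                observed = getattr(fv, name) / 100.0 * n
                slack = 3.0 * np.sqrt(n * p * (1 - p)) + 3.0
                assert abs(observed - n * p) <= slack, (
                    record.participant_id, name)

    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = S.GeneratorConfig(n_participants=3, tokens_min=200,
                                tokens_max=300, seed=11)
        a, b = tmp_path / "a", tmp_path / "b"
        S.generate_dataset(cfg, a)
        S.generate_dataset(cfg, b)
        for name in ["metadata.csv", "true_rates.csv", "manifest.json"]:
            assert (a / name).read_bytes() == (b / name).read_bytes()
        for pa in sorted((a / "corpus").iterdir()):
            assert pa.read_bytes() == (b / "corpus" / pa.name).read_bytes()

    def test_smallest_valid_dataset(self, tmp_path):
        cfg = S.GeneratorConfig(n_participants=2, tokens_min=50,
                                tokens_max=60, seed=0)
        out = S.generate_dataset(cfg, tmp_path / "tiny")
        assert len(list((out / "corpus").iterdir())) == 2


class TestFeatureMatrixFastPath:
    def test_group_means_track_truncated_normal_means(self):
        """Sample group means match the exact means of the group-conditional
        truncated normals (which exceed the nominal location parameter when
        the mass near zero is clipped)."""
        cfg = S.GeneratorConfig(n_participants=4000, seed=3)
        _, labels, matrix = S.generate_feature_matrix(cfg)
        sui = np.array([lab.suicidal_ideation for lab in labels])
        for group, mask in ((False, ~sui), (True, sui)):
            mean, sd = cfg.group_rates(group)["subjective_fpsp"]
            a = (0.0 - mean) / sd
            expected = sps.truncnorm(a, np.inf, loc=mean, scale=sd).mean()
            n = mask.sum()
            assert matrix.loc[mask, "subjective_fpsp"].mean() == pytest.approx(
                expected, abs=4 * sd / np.sqrt(n))

    def test_partition_identity_holds_rowwise(self):
        _, _, matrix = S.generate_feature_matrix(S.GeneratorConfig(seed=8))
        np.testing.assert_allclose(
            matrix["total_fpsp"],
            matrix[list(F.CASE_FEATURES)].sum(axis=1),
            rtol=0, atol=1e-12,
        )


def test_implied_or_matches_gaussian_closed_form():
    """With group-conditional laws far from the truncation point and equal
    SDs, the logistic projection slope reduces to (mu1 - mu0) / sigma^2."""
    cfg = S.GeneratorConfig().with_rates(
        non_suicidal={"verb": (20.0, 2.0)}, suicidal={"verb": (21.0, 2.0)})
    implied = S.implied_crude_or(cfg, "verb")
    closed_form = np.exp((21.0 - 20.0) / 4.0)
    assert implied == pytest.approx(closed_form, rel=1e-3)
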