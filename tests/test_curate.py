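"""Label curation: denoising rule, pseudo-labeling, balanced drafting."""

import numpy as np
import pytest

from pcai.curate import (
    Candidate,
    CurationConfig,
    CuratedDataset,
    LabeledSample,
    denoise,
    global_balanced_draft,
    pseudo_label,
    samples_from_cases,
    tma_balanced_draft,
)

from conftest import make_case


def S(sid, tma, label):
    return LabeledSample(sid, tma, label)


class TestDenoise:
    def test_rule_trace_on_thresholds(self):
        # a: label high, P(high)=0.05 < 0.1 -> discarded
        # b: label high, P(high)=0.95 -> kept
        # c: label low, P(low)=1-0.95=0.05 < 0.1 -> discarded
        samples = [S("a", "t", "high"), S("b", "t", "high"), S("c", "t", "low")]
        scores = {"a": 0.05, "b": 0.95, "c": 0.95}  # P(high)
        out = denoise(samples, scores, CurationConfig(denoise_disagreement_threshold=0.1))
        assert {d["sample_id"] for d in out.discarded} == {"a", "c"}
        assert {s.sample_id for s in out.kept} == {"b"}

    def test_low_label_uses_complement_probability(self):
        out = denoise(
            [S("c", "t", "low")], {"c": 0.95},
            CurationConfig(denoise_disagreement_threshold=0.1),
        )
        assert out.kept == [] and out.discarded[0]["sample_id"] == "c"

    def test_zero_threshold_discards_nothing(self):
        samples = [S("a", "t", "high"), S("b", "t", "low")]
        out = denoise(samples, {"a": 0.0, "b": 1.0},
                      CurationConfig(denoise_disagreement_threshold=0.0))
        assert out.kept == samples and out.discarded == []

    def test_missing_score_is_an_error(self):
        with pytest.raises(KeyError, match="a"):
            denoise([S("a", "t", "high")], {})

    def test_idempotent_on_own_output(self):
        samples = [S(f"s{i}", "t", "high" if i % 2 else "low") for i in range(10)]
        scores = {s.sample_id: 0.5 + 0.4 * (1 if s.label == "high" else -1) * ((i % 3) - 1)
                  for i, s in enumerate(samples)}
        config = CurationConfig(denoise_disagreement_threshold=0.3)
        once = denoise(samples, scores, config)
        twice = denoise(once.kept, scores, config)
        assert twice.kept == once.kept and twice.discarded == []

    def test_labels_never_change(self):
        samples = [S("a", "t", "high"), S("b", "t", "low")]
        out = denoise(samples, {"a": 0.9, "b": 0.2}, CurationConfig())
        assert {s.sample_id: s.label for s in out.kept} == {"a": "high", "b": "low"}


class TestPseudoLabel:
    def test_depletion_trace(self):
        # 6 high / 2 low confirmed; candidates 4.9, 4.5, 3.0 y: all added
        samples = [S(f"h{i}", "t", "high") for i in range(6)] + [
            S("l0", "t", "low"), S("l1", "t", "low")
        ]
        cands = [Candidate("p1", "t", 4.9), Candidate("p2", "t", 4.5), Candidate("p3", "t", 3.0)]
        out = pseudo_label(samples, cands)
        counts = out.label_counts()
        assert counts == {"high": 6, "low": 5}
        assert out.pseudo_labeled == ["p1", "p2", "p3"]

    def test_stops_at_balance_longest_follow_up_first(self):
        samples = [S("h0", "t", "high"), S("h1", "t", "high"), S("l0", "t", "low")]
        cands = [Candidate("p_short", "t", 1.0), Candidate("p_long", "t", 4.9)]
        out = pseudo_label(samples, cands)
        assert out.pseudo_labeled == ["p_long"]

    def test_follow_up_ties_broken_by_id(self):
        samples = [S("h0", "t", "high"), S("h1", "t", "high")]
        cands = [Candidate("pb", "t", 3.0), Candidate("pa", "t", 3.0), Candidate("pc", "t", 4.0)]
        out = pseudo_label(samples, cands)
        assert out.pseudo_labeled == ["pc", "pa"]

    def test_balanced_tma_gets_no_additions(self):
        samples = [S("h0", "t", "high"), S("l0", "t", "low")]
        assert pseudo_label(samples, [Candidate("p", "t", 4.0)]).pseudo_labeled == []

    def test_confirmable_candidate_rejected(self):
        with pytest.raises(ValueError, match="5"):
            pseudo_label([], [Candidate("p", "t", 6.0)])

    def test_idempotent_once_balanced_or_depleted(self):
        samples = [S("h0", "t", "high"), S("h1", "t", "high")]
        cands = [Candidate("p1", "t", 4.0)]
        once = pseudo_label(samples, cands)
        twice = pseudo_label(once.kept, [])
        assert twice.kept == once.kept and twice.pseudo_labeled == []

    def test_only_adds_lows(self):
        samples = [S("h0", "t", "high")] * 1
        out = pseudo_label(samples, [Candidate("p", "t", 2.0)])
        added = [s for s in out.kept if s.sample_id == "p"]
        assert added and added[0].label == "low"


class TestDrafting:
    def test_min_class_rule_per_tma(self, rng):
        samples = [S(f"h{i}", "A", "high") for i in range(8)] + [
            S(f"l{i}", "A", "low") for i in range(3)
        ]
        draft = tma_balanced_draft(samples, rng)
        assert len(draft) == 6
        labels = {s.sample_id: s.label for s in samples}
        assert sum(labels[d] == "high" for d in draft) == 3

    def test_fully_balanced_tma_drafted_whole(self, rng):
        samples = [S(f"h{i}", "A", "high") for i in range(5)] + [
            S(f"l{i}", "A", "low") for i in range(5)
        ]
        assert sorted(tma_balanced_draft(samples, rng)) == sorted(s.sample_id for s in samples)

    def test_single_class_tma_blocked(self, rng):
        samples = [S(f"h{i}", "A", "high") for i in range(7)]
        assert tma_balanced_draft(samples, rng) == []

    def test_every_epoch_draft_is_balanced_within_each_tma(self, rng):
        samples = []
        for tma, (nh, nl) in {"A": (5, 2), "B": (1, 6), "C": (4, 4), "D": (3, 0)}.items():
            samples += [S(f"{tma}h{i}", tma, "high") for i in range(nh)]
            samples += [S(f"{tma}l{i}", tma, "low") for i in range(nl)]
        labels = {s.sample_id: s.label for s in samples}
        tmas = {s.sample_id: s.tma_id for s in samples}
        for _ in range(20):
            draft = tma_balanced_draft(samples, rng)
            assert len(draft) == len(set(draft))  # without replacement
            for tma in "ABCD":
                highs = sum(1 for d in draft if tmas[d] == tma and labels[d] == "high")
                lows = sum(1 for d in draft if tmas[d] == tma and labels[d] == "low")
                assert highs == lows

    def test_global_draft_ignores_tma(self, rng):
        samples = [S(f"h{i}", "A", "high") for i in range(6)] + [S("l0", "B", "low")]
        draft = global_balanced_draft(samples, rng)
        assert len(draft) == 2 and "l0" in draft


class TestSamplesFromCases:
    def test_partition_into_labeled_and_candidates(self):
        cases = [
            make_case(case_id="hi", bcr_flag=True, t_bcr=1.0, follow_up_years=1.0),
            make_case(case_id="lo", follow_up_years=7.0),
            make_case(case_id="maybe", follow_up_years=4.0),
            make_case(case_id="late", bcr_flag=True, t_bcr=4.5, follow_up_years=4.5),
        ]
        labeled, candidates = samples_from_cases(cases, "train")
        assert {s.sample_id: s.label for s in labeled} == {"hi": "high", "lo": "low"}
        assert [c.sample_id for c in candidates] == ["maybe"]  # late bad outcome is no candidate


def test_curated_dataset_guards_overlap():
    with pytest.raises(ValueError):
        CuratedDataset(kept=[S("a", "t", "high")], discarded=[{"sample_id": "a"}])
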