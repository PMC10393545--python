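import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammatail import Peptide
from gammatail.errors import InvalidInputError, ScorerContractError
from gammatail.mutpath import (
    MutationPath,
    enumerate_insertions,
    enumerate_substitutions,
    greedy_helix_path,
    isometric_controls,
    load_physchem_classes,
)
from gammatail.seqmetrics import apply_edits, helix_percent, predict_ss


def brute_force_path(wt, scorer, max_steps=50, allow_insertions=False):
    """Independent oracle: materialise every variant, take argmax per step."""
    current, score = wt, scorer(wt)
    trace = []
    while len(trace) < max_steps:
        subs = enumerate_substitutions(current)
        scored = [(scorer(v), pos, aa, v) for pos, aa, v in subs]
        best = max(scored, key=lambda t: (t[0], -t[1], -ord(t[2])))
        # recompute argmax with the stated tie-break: lowest position, then aa
        top = max(s for s, *_ in scored)
        winners = [t for t in scored if t[0] == top]
        winners.sort(key=lambda t: (t[1], t[2]))
        s, pos, aa, v = winners[0]
        if s > score:
            trace.append(("substitution", pos, aa, v.sequence, s))
            current, score = v, s
            continue
        if allow_insertions:
            scored = [(scorer(v), pos, aa, v) for pos, aa, v in enumerate_insertions(current)]
            top = max(x for x, *_ in scored)
            winners = sorted([t for t in scored if t[0] == top], key=lambda t: (t[1], t[2]))
            s, pos, aa, v = winners[0]
            if s > score:
                trace.append(("insertion", pos, aa, v.sequence, s))
                current, score = v, s
                continue
        break
    return trace


class TestEnumeration:
    @pytest.mark.parametrize("seq,n", [("GG", 38), ("GGG", 57)])
    def test_substitution_counts(self, seq, n):
        variants = enumerate_substitutions(Peptide("t", seq))
        assert len(variants) == n
        for pos, aa, v in variants:
            assert sum(a != b for a, b in zip(seq, v.sequence)) == 1
            assert v.sequence[pos - 1] == aa

    def test_insertion_counts_and_inverse(self):
        pep = Peptide("t", "GAL")
        variants = enumerate_insertions(pep)
        assert len(variants) == 80  # 20 x (L+1)
        for pos, aa, v in variants:
            assert len(v) == 4
            assert v.sequence[: pos - 1] + v.sequence[pos:] == pep.sequence


class TestGreedyPath:
    def test_counting_scorer_on_ggg(self, counting_scorer):
        path = greedy_helix_path(Peptide("wt", "GGG"), counting_scorer)
        assert [s.result.sequence for s in path.steps] == ["AGG", "AAG", "AAA"]
        assert [s.helix_pct for s in path.steps] == pytest.approx([100 / 3, 200 / 3, 100.0])

    def test_immediate_plateau_gives_empty_path(self, counting_scorer):
        path = greedy_helix_path(Peptide("wt", "AAAA"), counting_scorer)
        assert path.steps == ()
        assert path.final.sequence == "AAAA"

    def test_tie_break_lowest_position_then_alphabet(self):
        # every substitution to A or C scores the same: position 1, residue A wins
        scorer = lambda p: 100.0 * sum(c in "AC" for c in p.sequence) / len(p)
        path = greedy_helix_path(Peptide("wt", "GG"), scorer)
        assert path.steps[0].position == 1 and path.steps[0].to_aa == "A"

    def test_insertions_unlock_only_at_substitution_plateau(self):
        # scorer saturates under substitutions at length 3, then rewards length
        scorer = lambda p: p.sequence.count("A") + 0.5 * len(p)
        path = greedy_helix_path(Peptide("wt", "GGG"), scorer, max_steps=4, allow_insertions=True)
        kinds = [s.kind for s in path.steps]
        assert kinds == ["substitution"] * 3 + ["insertion"]

    def test_nondeterministic_scorer_detected(self):
        calls = iter(range(100))
        scorer = lambda p: float(next(calls))
        with pytest.raises(ScorerContractError):
            greedy_helix_path(Peptide("wt", "GGG"), scorer)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle_on_short_peptides(self, seed, counting_scorer):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        wt = Peptide("wt", seq)
        path = greedy_helix_path(wt, counting_scorer, allow_insertions=True)
        oracle = brute_force_path(wt, counting_scorer, allow_insertions=True)
        got = [(s.kind, s.position, s.to_aa, s.result.sequence, s.helix_pct) for s in path.steps]
        assert got == oracle

    def test_replay_invariant_with_real_predictor(self):
        wt = Peptide("wt", "GSGSGSGSGS")
        scorer = lambda p: helix_percent(predict_ss(p))
        path = greedy_helix_path(wt, scorer, max_steps=6, allow_insertions=True)
        assert apply_edits(wt, path.edits()) == path.final.sequence
        pcts = [s.helix_pct for s in path.steps]
        assert all(b > a for a, b in zip(pcts, pcts[1:]))


class TestIsometricControls:
    def test_controls_differ_only_at_edit_positions(self, counting_scorer):
        wt = Peptide("wt", "GGGGG")
        path = greedy_helix_path(wt, counting_scorer, max_steps=2)
        c1 = isometric_controls(path, counting_scorer, "C1")
        positions = {s.position for s in path.steps}
        diff = {i + 1 for i, (a, b) in enumerate(zip(wt.sequence, c1.sequence)) if a != b}
        assert diff == positions

    def test_c1_minimises_helix_content(self):
        # random 10-mers whose greedy path is nonempty: the disorder-preserving
        # control must not gain helix content over the wildtype
        scorer = lambda p: helix_percent(predict_ss(p))
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 5:
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
            wt = Peptide("wt", seq)
            path = greedy_helix_path(wt, scorer, max_steps=4)
            if not path.steps:
                continue
            c1 = isometric_controls(path, scorer, "C1")
            assert scorer(c1) <= scorer(wt) + 5.0
            checked += 1

    def test_c2_stays_within_class(self, counting_scorer):
        wt = Peptide("wt", "LLLLL")
        path = greedy_helix_path(wt, counting_scorer, max_steps=3)
        classes = load_physchem_classes()
        c2 = isometric_controls(path, counting_scorer, "C2", classes)
        cls_of = {aa: members for members in classes.values() for aa in members}
        for i, (a, b) in enumerate(zip(wt.sequence, c2.sequence)):
            if a != b:
                assert b in cls_of[a] and b != a

    def test_empty_path_rejected(self, counting_scorer):
        path = MutationPath(Peptide("wt", "AAA"), ())
        with pytest.raises(InvalidInputError):
            isometric_controls(path, counting_scorer, "C1")


def test_path_invariants_enforced(counting_scorer):
    wt = Peptide("wt", "GGG")
    good = greedy_helix_path(wt, counting_scorer)
    # tampering with the score ordering must be rejected on construction
    bad_steps = (good.steps[1], good.steps[0], good.steps[2])
    with pytest.raises(InvalidInputError):
        MutationPath(wt, bad_steps)
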