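import logging
import math

import numpy as np
import pytest

from hmmvar import (
    Call,
    DomainHit,
    Method,
    ModelSource,
    Prediction,
    PredictConfig,
    Substitution,
    ValidationError,
    WeightTable,
    classify,
    identity_hit,
    predict,
    unweighted_score,
    weighted_score,
)
from hmmvar.domains import INSERT
from hmmvar.profile_hmm import AMINO_ALPHABET, SOURCE_PRIORITY

from conftest import make_model, point_mass_rows


class TestUnweightedScore:
    def test_equal_probabilities_score_zero(self):
        assert unweighted_score(0.3, 0.3) == 0.0
        assert unweighted_score(0.3, 0.3, formula="odds") == 0.0

    def test_probability_drop_is_negative(self):
        assert unweighted_score(0.8, 0.2) == pytest.approx(math.log(0.25))

    def test_probability_gain_is_positive(self):
        assert unweighted_score(0.2, 0.8) == pytest.approx(math.log(4.0))

    @pytest.mark.parametrize("formula", ["ratio", "odds"])
    def test_antisymmetry(self, formula):
        rng = np.random.default_rng(5)
        for _ in range(100):
            pw, pm = rng.uniform(1e-6, 1 - 1e-6, size=2)
            assert unweighted_score(pw, pm, formula=formula) == pytest.approx(
                -unweighted_score(pm, pw, formula=formula), abs=1e-12
            )

    @pytest.mark.parametrize("formula", ["ratio", "odds"])
    def test_monotone_in_each_argument(self, formula):
        grid = np.linspace(0.05, 0.95, 10)
        scores_up = [unweighted_score(0.4, pm, formula=formula) for pm in grid]
        assert all(a < b for a, b in zip(scores_up, scores_up[1:]))
        scores_down = [unweighted_score(pw, 0.4, formula=formula) for pw in grid]
        assert all(a > b for a, b in zip(scores_down, scores_down[1:]))

    def test_zero_probability_floored_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="hmmvar.scoring"):
            value = unweighted_score(0.5, 0.0)
        assert math.isfinite(value)
        assert value == pytest.approx(math.log(1e-10 / 0.5))
        assert "floored" in caplog.text

    def test_unknown_formula_rejected(self):
        with pytest.raises(ValidationError):
            unweighted_score(0.5, 0.5, formula="linear")


class TestWeightedScore:
    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            pw, pm = rng.uniform(1e-6, 1 - 1e-6, size=2)
            w = rng.uniform(0.5, 50)
            assert weighted_score(pw, pm, w, w) == pytest.approx(
                unweighted_score(pw, pm), abs=1e-12
            )

    def test_hand_case(self):
        assert weighted_score(0.5, 0.5, w_d=10.0, w_n=5.0) == pytest.approx(
            math.log(0.5)
        )

    def test_offset_identity_for_default_pair(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            pw, pm = rng.uniform(1e-6, 1 - 1e-6, size=2)
            w_d, w_n = rng.uniform(0.5, 100, size=2)
            assert weighted_score(pw, pm, w_d, w_n) - unweighted_score(pw, pm) == (
                pytest.approx(math.log(w_n / w_d), abs=1e-12)
            )

    @pytest.mark.parametrize("formula", ["ratio", "odds"])
    def test_monotone_in_weights(self, formula):
        w_grid = np.linspace(1.0, 30.0, 8)
        rising_wd = [
            weighted_score(0.3, 0.4, w_d, 5.0, formula=formula) for w_d in w_grid
        ]
        assert all(a > b for a, b in zip(rising_wd, rising_wd[1:]))
        rising_wn = [
            weighted_score(0.3, 0.4, 5.0, w_n, formula=formula) for w_n in w_grid
        ]
        assert all(a < b for a, b in zip(rising_wn, rising_wn[1:]))

    @pytest.mark.parametrize("w_d, w_n", [(0.0, 1.0), (1.0, 0.0), (-2.0, 1.0)])
    def test_nonpositive_weights_rejected(self, w_d, w_n):
        with pytest.raises(ValidationError):
            weighted_score(0.5, 0.5, w_d, w_n)


class TestClassify:
    def test_below_threshold_is_damaging(self):
        assert classify(-3.1, -3.0) is Call.DAMAGING

    def test_tie_is_tolerated(self):
        assert classify(-1.5, -1.5) is Call.TOLERATED
        assert classify(-3.0, -3.0) is Call.TOLERATED

    def test_zero_is_tolerated_at_both_defaults(self):
        assert classify(0.0, -3.0) is Call.TOLERATED
        assert classify(0.0, -1.5) is Call.TOLERATED

    def test_absent_score_is_no_prediction(self):
        assert classify(None, -3.0) is Call.NO_PREDICTION


@pytest.fixture
def peaked_setup():
    """One domain model with all mass on the wild-type residue at each state."""
    residues = [0, 4, 7]  # A, F, H
    emissions = 0.999 * point_mass_rows(residues) + 0.001 / 20
    model = make_model(emissions, model_id="PEAK", source=ModelSource.PFAM_A)
    hit = identity_hit("P1", model, e_value=1e-9)
    return model, hit


class TestPredict:
    def test_conserved_wild_type_scores_strongly_negative(self, peaked_setup):
        model, hit = peaked_setup
        sub = Substitution("P1", 2, "F", "C")
        p = predict(sub, [hit], {"PEAK": model})
        assert p.call is Call.DAMAGING
        assert p.score < -3.0
        assert p.model_id == "PEAK" and p.state_index == 2
        assert p.p_wild == pytest.approx(0.99905)
        assert p.p_mutant == pytest.approx(5e-5)

    def test_outside_all_domains_weighted_gives_no_prediction(self, peaked_setup):
        model, hit = peaked_setup
        sub = Substitution("OTHER", 2, "F", "C")
        weights = WeightTable(counts={"PEAK": (3, 1)})
        p = predict(sub, [hit], {"PEAK": model}, weights=weights)
        assert p.call is Call.NO_PREDICTION
        assert p.score is None and p.model_id is None

    def test_weighted_mode_excludes_ab_initio_models(self, peaked_setup):
        model, hit = peaked_setup
        whole = make_model(
            np.full((3, 20), 0.05), model_id="ABI", source=ModelSource.AB_INITIO
        )
        abi_hit = identity_hit("P1", whole, e_value=0.0)
        library = {"PEAK": model, "ABI": whole}
        sub = Substitution("P1", 2, "F", "C")
        weights = WeightTable(counts={})
        p_weighted = predict(sub, [abi_hit], library, weights=weights)
        assert p_weighted.call is Call.NO_PREDICTION
        # unweighted mode happily scores against the whole-protein model
        p_unweighted = predict(sub, [abi_hit], library)
        assert p_unweighted.model_id == "ABI"
        assert p_unweighted.score == pytest.approx(0.0)

    def test_most_informative_model_wins(self, peaked_setup):
        model, hit = peaked_setup
        flat = make_model(np.full((3, 20), 0.05), model_id="FLAT")
        flat_hit = identity_hit("P1", flat, e_value=1e-9)
        p = predict(Substitution("P1", 2, "F", "C"), [flat_hit, hit],
                    {"PEAK": model, "FLAT": flat})
        assert p.model_id == "PEAK"

    def test_insignificant_hit_gives_no_prediction(self, peaked_setup):
        model, hit_sig = peaked_setup
        weak = DomainHit("P1", "PEAK", 0.5, 1, 3, {1: 1, 2: 2, 3: 3})
        p = predict(Substitution("P1", 2, "F", "C"), [weak], {"PEAK": model})
        assert p.call is Call.NO_PREDICTION

    def test_weighted_threshold_and_offset(self, peaked_setup):
        model, hit = peaked_setup
        weights = WeightTable(counts={"PEAK": (9, 4)})  # W_d=10, W_n=5
        sub = Substitution("P1", 2, "F", "C")
        unweighted = predict(sub, [hit], {"PEAK": model})
        weighted = predict(sub, [hit], {"PEAK": model}, weights=weights)
        assert weighted.threshold == -1.5
        assert unweighted.threshold == -3.0
        assert weighted.score == pytest.approx(
            unweighted.score + math.log(5.0 / 10.0)
        )

    def test_low_support_flag_on_vanishing_wild_type(self):
        emissions = point_mass_rows([0])  # P(A)=1, everything else exactly 0
        model = make_model(emissions, model_id="HARD")
        hit = identity_hit("P1", model)
        p = predict(Substitution("P1", 1, "C", "D"), [hit], {"HARD": model})
        assert p.low_support
        assert math.isfinite(p.score)

    def test_deterministic(self, peaked_setup):
        model, hit = peaked_setup
        sub = Substitution("P1", 3, "H", "W")
        assert predict(sub, [hit], {"PEAK": model}) == predict(
            sub, [hit], {"PEAK": model}
        )

    def test_prediction_invariants_enforced(self):
        sub = Substitution("P", 1, "A", "C")
        with pytest.raises(ValidationError):
            Prediction(sub, Method.UNWEIGHTED, Call.NO_PREDICTION, -3.0, score=1.0)
        with pytest.raises(ValidationError):
            Prediction(sub, Method.UNWEIGHTED, Call.DAMAGING, -3.0, score=1.0)


# ---------------------------------------------------------------------------
# Independent end-to-end oracle


def oracle_predict(sub, hits, library, weights, config):
    """Re-derive a prediction by explicit enumeration, independently of the
    pipeline: inline e-value filtering, state lookup, 20-term KL, ranking and
    log-ratio arithmetic."""
    candidates = []
    for hit in hits:
        if hit.e_value > config.e_threshold or hit.protein_id != sub.protein_id:
            continue
        if not (hit.ali_from <= sub.position <= hit.ali_to):
            continue
        state = hit.state_map.get(sub.position)
        if state is None:
            continue
        model = library.get(hit.model_id)
        if model is None or state > model.length:
            continue
        if weights is not None and model.source is ModelSource.AB_INITIO:
            continue
        row = model.match_emissions[state - 1]
        if config.background is not None:
            q = config.background.probabilities
        elif model.compo is not None:
            q = model.compo / model.compo.sum()
        else:
            q = np.full(20, 0.05)
        ic = sum(
            row[a] * math.log(row[a] / q[a]) for a in range(20) if row[a] > 0
        )
        candidates.append((max(ic, 0.0), model, state, row))
    if not candidates:
        return None
    candidates.sort(
        key=lambda c: (-c[0], SOURCE_PRIORITY[c[1].source], c[1].model_id)
    )
    _, model, state, row = candidates[0]
    eps = config.epsilon
    pw = max(row[model.alphabet.index(sub.wild_type)], eps)
    pm = max(row[model.alphabet.index(sub.mutant)], eps)
    if weights is None:
        score = math.log(pm / pw)
    else:
        c_d, c_n = weights.counts.get(model.model_id, (0, 0))
        score = math.log((pm * (c_n + 1.0)) / (pw * (c_d + 1.0)))
    return model.model_id, state, score


def random_fixture(seed):
    """A randomized universe of models, hits (with inserts/deletions) and a sub."""
    rng = np.random.default_rng(seed)
    n_models = int(rng.integers(1, 5))
    library = {}
    for i in range(n_models):
        length = int(rng.integers(3, 15))
        alpha = float(rng.choice([0.1, 0.5, 2.0]))
        emissions = rng.dirichlet(np.full(20, alpha), size=length)
        source = ModelSource(
            str(rng.choice(["superfamily", "pfam_a", "pfam_b", "ab_initio"]))
        )
        library[f"R{i}"] = make_model(emissions, model_id=f"R{i}", source=source)
    hits = []
    for i, (mid, model) in enumerate(library.items()):
        ali_from = int(rng.integers(1, 6))
        state_map, pos, state = {}, ali_from, int(rng.integers(1, 3))
        while state <= model.length:
            op = rng.choice(["M", "M", "M", "I", "D"])
            if op == "M":
                state_map[pos] = state
                pos += 1
                state += 1
            elif op == "I":
                state_map[pos] = INSERT
                pos += 1
            else:
                state += 1
        if not any(v is not None for v in state_map.values()):
            state_map[pos] = model.length
            pos += 1
        hits.append(
            DomainHit("PX", mid, float(rng.choice([1e-8, 0.005, 0.01, 0.3])),
                      ali_from, pos - 1, state_map)
        )
    position = int(rng.integers(1, 20))
    wt, mut = rng.choice(20, size=2, replace=False)
    sub = Substitution("PX", position, AMINO_ALPHABET[wt], AMINO_ALPHABET[mut])
    weights = None
    if rng.random() < 0.5:
        counts = {
            mid: (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
            for mid in library
            if rng.random() < 0.7
        }
        weights = WeightTable(counts=counts)
    return sub, hits, library, weights


@pytest.mark.parametrize("seed", range(40))
def test_predict_agrees_with_enumeration_oracle(seed):
    sub, hits, library, weights = random_fixture(seed)
    config = PredictConfig()
    expected = oracle_predict(sub, hits, library, weights, config)
    got = predict(sub, hits, library, weights=weights, config=config)
    if expected is None:
        assert got.call is Call.NO_PREDICTION
    else:
        model_id, state, score = expected
        assert (got.model_id, got.state_index) == (model_id, state)
        assert got.score == pytest.approx(score, abs=1e-9)
        assert got.call is classify(score, got.threshold)
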