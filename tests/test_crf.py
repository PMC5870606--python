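"""Linear-chain CRF: gradient correctness, learning, determinism, persistence."""

import numpy as np
import pytest
from scipy import optimize

from mutmention import LinearChainCRF


def _random_problem(rng, n_seqs=4):
    labels = ["B", "I", "E", "O"]
    X, y = [], []
    for _ in range(n_seqs):
        n = int(rng.integers(1, 6))
        X.append(
            [{f"f{rng.integers(0, 6)}": float(rng.normal()), "bias": 1.0}
             for _ in range(n)]
        )
        y.append([labels[rng.integers(0, 4)] for _ in range(n)])
    return X, y


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    X, y = _random_problem(rng)
    crf = LinearChainCRF(c2=0.05)
    crf._build_index(X)
    Xm, lengths = crf._design(X)
    XmT = Xm.T.tocsr()
    l2i = {l: i for i, l in enumerate(crf.labels)}
    y_flat = np.array([l2i[l] for s in y for l in s])
    theta = rng.normal(size=Xm.shape[1] * 4 + 16 + 8) * 0.3
    err = optimize.check_grad(
        lambda t: crf._nll_grad(t, Xm, XmT, lengths, y_flat)[0],
        lambda t: crf._nll_grad(t, Xm, XmT, lengths, y_flat)[1],
        theta,
    )
    assert err < 1e-4


def _separable_problem(rng, n=40):
    X, y = [], []
    for _ in range(n):
        length = int(rng.integers(3, 8))
        seq, ys, state = [], [], "O"
        for t in range(length):
            if state == "O" and rng.random() < 0.3 and t < length - 1:
                seq.append({"w=start": 1.0}); ys.append("B"); state = "M"
            elif state == "M":
                seq.append({"w=end": 1.0}); ys.append("E"); state = "O"
            else:
                seq.append({"w=filler": 1.0}); ys.append("O")
        X.append(seq); y.append(ys)
    return X, y


def test_fits_separable_sequences_perfectly():
    rng = np.random.default_rng(1)
    X, y = _separable_problem(rng)
    crf = LinearChainCRF(max_iter=100).fit(X, y)
    assert crf.predict(X) == [list(s) for s in y]


def test_training_is_deterministic():
    rng = np.random.default_rng(2)
    X, y = _separable_problem(rng, n=20)
    a = LinearChainCRF().fit(X, y)
    b = LinearChainCRF().fit(X, y)
    np.testing.assert_array_equal(a.W, b.W)
    assert a.predict(X) == b.predict(X)


def test_real_valued_features_used():
    # two states distinguishable only through a real-valued feature
    rng = np.random.default_rng(3)
    X, y = [], []
    for _ in range(60):
        v = float(rng.normal())
        X.append([{"x": v, "bias": 1.0}])
        y.append(["B" if v > 0 else "O"])
    crf = LinearChainCRF().fit(X, y)
    assert crf.predict([[{"x": 2.0, "bias": 1.0}]]) == [["B"]]
    assert crf.predict([[{"x": -2.0, "bias": 1.0}]]) == [["O"]]


def test_untrained_predict_and_empty_fit_rejected():
    crf = LinearChainCRF()
    with pytest.raises(RuntimeError):
        crf.predict([[{"a": 1.0}]])
    with pytest.raises(ValueError):
        crf.fit([], [])


def test_unknown_features_ignored_at_predict_time():
    rng = np.random.default_rng(4)
    X, y = _separable_problem(rng, n=20)
    crf = LinearChainCRF().fit(X, y)
    seq = [{"w=start": 1.0, "never_seen": 5.0}, {"w=end": 1.0}]
    assert crf.predict([seq]) == [["B", "E"]]


def test_round_trip_serialization(tmp_path):
    rng = np.random.default_rng(5)
    X, y = _separable_problem(rng, n=15)
    crf = LinearChainCRF().fit(X, y)
    path = tmp_path / "crf.json"
    crf.save(path)
    loaded = LinearChainCRF.load(path)
    assert loaded.predict(X) == crf.predict(X)
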