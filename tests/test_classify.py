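"""Classification protocol: features, selection, folds, SVM, metrics, fusion."""

import numpy as np
import pytest
from scipy import stats

from pcn import (
    AdjacencyMatrix,
    LabeledDataset,
    ScanRecord,
    ValidationError,
    evaluate_metrics,
    fuse_probabilities,
    pearson_bfn,
    run_experiment,
    select_lambda,
    subject_level_folds,
    train_probabilistic_classifier,
    ttest_select,
    vectorize_edges,
)
from pcn.classify import PlattCalibratedLinearSVM


def _adj(values, order=1):
    return AdjacencyMatrix(values=np.asarray(values, dtype=float), order=order)


def _random_adj(rng, n, order=1):
    from pcn import ROITimeSeries

    ts = ROITimeSeries(values=rng.standard_normal((n + 5, n)))
    R = pearson_bfn(ts)
    return AdjacencyMatrix(values=R.values, order=order)


def _toy_dataset(rng, n_subjects=40, n_rois=8, signal=1.0, orders=(1,),
                 scans_per_subject=1, positive="positive"):
    """Group-dependent random adjacency matrices: the positive group's
    edge (0, 1) is shifted toward +1 by `signal`."""
    scans = []
    for g, label in ((0, "negative"), (1, positive)):
        for s in range(n_subjects // 2):
            subj = f"{label[:3]}{s}"
            for sc in range(scans_per_subject):
                mats = {}
                for o in orders:
                    R = _random_adj(rng, n_rois, order=1).values.copy()
                    if g == 1 and o == orders[0]:
                        R[0, 1] = R[1, 0] = np.clip(R[0, 1] + signal, -1, 1)
                    mats[o] = AdjacencyMatrix(values=R, order=1)
                scans.append(ScanRecord(matrices=mats, subject_id=subj, label=label))
    return LabeledDataset(scans=tuple(scans), positive_class_name=positive)


# ------------------------------------------------------------------ features


def test_vectorize_edges_ordering():
    R = _adj([[1, 0.2, 0.3], [0.2, 1, 0.4], [0.3, 0.4, 1]])
    np.testing.assert_array_equal(vectorize_edges(R), [0.2, 0.3, 0.4])


def test_vectorize_edges_length_and_roundtrip(rng):
    R = _random_adj(rng, 116)
    v = vectorize_edges(R)
    assert v.shape == (6670,)
    # triangle-unflatten oracle reproduces the off-diagonals
    back = np.eye(116)
    back[np.triu_indices(116, 1)] = v
    back = back + np.triu(back, 1).T
    np.testing.assert_array_equal(back, R.values)


# ----------------------------------------------------------------- selection


def test_ttest_null_and_overwhelming_effect(rng):
    F = rng.standard_normal((40, 50))
    F[20:] = F[:20]  # the two groups are identical on every edge
    y = np.repeat([0, 1], 20)
    with pytest.warns(UserWarning):
        sel = ttest_select(F, y, 0.001)
    assert sel.size == 0
    F2 = rng.standard_normal((100, 20))
    y2 = np.repeat([0, 1], 50)
    F2[y2 == 1, 7] += 10.0  # 10 pooled SDs on one edge
    sel2 = ttest_select(F2, y2, 0.001)
    assert 7 in sel2


def test_ttest_matches_direct_formula(rng):
    n1 = n2 = 20
    F = rng.standard_normal((n1 + n2, 100))
    y = np.repeat([0, 1], [n1, n2])
    true = rng.choice(100, 5, replace=False)
    F[y == 1][:, true]  # no-op; make shift explicitly below
    F[n1:, true] += 1.5
    sel = set(ttest_select(F, y, 0.001).tolist())
    # from-scratch pooled-variance t statistic and p-value
    oracle = set()
    for j in range(100):
        a, b = F[:n1, j], F[n1:, j]
        sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        if p < 0.001:
            oracle.add(j)
    assert sel == oracle
    assert len(oracle & set(true.tolist())) >= 3  # most planted effects found


def test_ttest_single_class_error(rng):
    with pytest.raises(ValidationError):
        ttest_select(rng.standard_normal((10, 5)), np.zeros(10, dtype=int), 0.05)


# --------------------------------------------------------------------- folds


def test_fold_sizes_143_subjects(rng):
    # 143 subjects into 5 folds: 143 = 5 * 28 + 3
    scans = []
    for i in range(143):
        label = "positive" if i < 72 else "negative"
        mats = {1: _random_adj(rng, 4)}
        scans.append(ScanRecord(matrices=mats, subject_id=f"s{i:03d}", label=label))
    ds = LabeledDataset(scans=tuple(scans))
    split = subject_level_folds(ds, k=5, seed=3)
    assert sorted(split.fold_sizes()) == [28, 28, 29, 29, 29]


def test_subject_scans_share_fold_and_determinism(rng):
    ds = _toy_dataset(rng, n_subjects=20, scans_per_subject=4)
    a = subject_level_folds(ds, k=5, seed=11)
    b = subject_level_folds(ds, k=5, seed=11)
    assert a.assignments == b.assignments
    for fold in range(5):
        te = a.test_indices(ds, fold)
        tr = a.train_indices(ds, fold)
        te_subj = {ds.scans[i].subject_id for i in te}
        tr_subj = {ds.scans[i].subject_id for i in tr}
        assert not (te_subj & tr_subj)
    c = subject_level_folds(ds, k=5, seed=12)
    assert c.assignments != a.assignments  # different seed reshuffles


def test_too_few_subjects(rng):
    ds = _toy_dataset(rng, n_subjects=4)
    with pytest.raises(ValidationError):
        subject_level_folds(ds, k=5, seed=0)


# ---------------------------------------------------------------- classifier


def test_classifier_separable_and_symmetric(rng):
    X = np.vstack([rng.normal(-2, 0.1, (20, 2)), rng.normal(2, 0.1, (20, 2))])
    y = np.repeat([0, 1], 20)
    clf = train_probabilistic_classifier(X, y)
    assert np.mean((clf.predict_proba(X) >= 0.5) == y) == 1.0
    flipped = train_probabilistic_classifier(X, 1 - y)
    np.testing.assert_allclose(
        flipped.decision_function(X), -clf.decision_function(X), atol=1e-6
    )
    np.testing.assert_allclose(
        flipped.predict_proba(X), 1 - clf.predict_proba(X), atol=1e-4
    )


def test_classifier_determinism_and_fallback(rng):
    X = rng.standard_normal((30, 5))
    y = (rng.random(30) > 0.5).astype(int)
    y[:2] = [0, 1]
    a = train_probabilistic_classifier(X, y).predict_proba(X)
    b = train_probabilistic_classifier(X, y).predict_proba(X)
    np.testing.assert_array_equal(a, b)
    with pytest.warns(UserWarning):
        empty = PlattCalibratedLinearSVM().fit(np.empty((30, 0)), y)
    np.testing.assert_allclose(empty.predict_proba(np.empty((4, 0))), np.mean(y))


# ------------------------------------------------------------------- metrics


def test_metrics_arithmetic():
    # TP=3 TN=2 FP=1 FN=2
    probs = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.9])
    y = np.array([1, 1, 1, 1, 1, 0, 0, 0])
    m = evaluate_metrics(probs, y)
    assert (m.tp, m.tn, m.fp, m.fn) == (3, 2, 1, 2)
    assert m.acc == pytest.approx(0.625)
    assert m.sen == pytest.approx(0.6)
    assert m.spe == pytest.approx(2 / 3)
    # metrics recompute exactly from the stored counts
    assert m.acc == (m.tp + m.tn) / (m.tp + m.tn + m.fp + m.fn)
    assert m.sen == m.tp / (m.tp + m.fn)
    assert m.spe == m.tn / (m.tn + m.fp)


def test_metrics_edge_cases():
    y = np.array([1, 1, 0, 0])
    perfect = evaluate_metrics(np.array([0.9, 0.8, 0.1, 0.2]), y)
    assert perfect.acc == perfect.sen == perfect.spe == 1.0
    allpos = evaluate_metrics(np.ones(4), y)
    assert allpos.sen == 1.0 and allpos.spe == 0.0
    onlypos = evaluate_metrics(np.ones(2), np.ones(2, dtype=int))
    assert np.isnan(onlypos.spe) and "SPE" in onlypos.undefined


# -------------------------------------------------------------------- fusion


def test_fuse_probabilities_convexity():
    O1 = np.array([0.8, 0.2])
    O2 = np.array([0.4, 0.6])
    np.testing.assert_array_equal(fuse_probabilities(O1, O2, 1.0), O1)
    assert fuse_probabilities(O1, O2, 0.5)[0] == pytest.approx(0.6)
    np.testing.assert_allclose(fuse_probabilities(O1, O1, 0.3), O1, atol=1e-15)
    with pytest.raises(ValidationError):
        fuse_probabilities(O1, O2, 1.5)


def test_select_lambda_tie_and_singleton(rng):
    ds = _toy_dataset(rng, n_subjects=30, orders=(1, 2), signal=1.2)
    # identical channels: every lambda ties; tie-break returns 0.5
    for s in ds.scans:
        s.matrices[2] = s.matrices[1]
    assert select_lambda(ds, 2, 0.05, seed=1) == 0.5
    assert select_lambda(ds, 2, 0.05, grid=[0.3], seed=1) == 0.3


def test_select_lambda_prefers_informative_channel(rng):
    wins = 0
    for trial in range(10):
        ds = _toy_dataset(rng, n_subjects=30, orders=(1, 2), signal=1.2)
        # order 2 = pure noise (already group-independent by construction)
        lam = select_lambda(ds, 2, 0.05, seed=trial)
        wins += lam >= 0.5
    assert wins >= 7  # O1 informative -> high lambda in the majority of runs


# ------------------------------------------------------------ run_experiment


def test_run_experiment_single_mode_recovers_signal(rng):
    ds = _toy_dataset(rng, n_subjects=40, signal=1.2)
    res = run_experiment(ds, orders=[1], p_grid=[0.05], k=5, seed=0)
    m = res[(1, 0.05)]
    assert m.acc > 0.8
    assert len(m.per_fold) == 5
    assert sum(f.tp + f.tn + f.fp + f.fn for f in m.per_fold) == len(ds)


def test_run_experiment_deterministic(rng):
    ds = _toy_dataset(rng, n_subjects=30, signal=0.8)
    a = run_experiment(ds, orders=[1], p_grid=[0.05], k=5, seed=4)[(1, 0.05)]
    b = run_experiment(ds, orders=[1], p_grid=[0.05], k=5, seed=4)[(1, 0.05)]
    assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)


def test_run_experiment_permuted_labels_chance(rng):
    ds = _toy_dataset(rng, n_subjects=40, signal=1.2)
    # permute labels across subjects: signal decouples from class
    labels = [s.label for s in ds.scans]
    perm = rng.permutation(len(labels))
    scans = tuple(
        ScanRecord(matrices=s.matrices, subject_id=s.subject_id,
                   label=labels[perm[i]])
        for i, s in enumerate(ds.scans)
    )
    accs = []
    for seed in range(3):
        ds_perm = LabeledDataset(scans=scans)
        res = run_experiment(ds_perm, orders=[1], p_grid=[0.05], k=5, seed=seed)
        accs.append(res[(1, 0.05)].acc)
    assert 0.3 <= np.mean(accs) <= 0.7


def test_run_experiment_fusion_mode(rng):
    ds = _toy_dataset(rng, n_subjects=30, orders=(1, 2), signal=1.2)
    res = run_experiment(ds, orders=[2], p_grid=[0.05], mode="fusion",
                         k=3, seed=0, inner_k=3)
    fr = res[("2&1", 0.05)]
    assert len(fr.lambda_selected) == 3
    assert all(l in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
               for l in fr.lambda_selected)
    assert np.all((fr.fused_probabilities >= 0) & (fr.fused_probabilities <= 1))
    assert fr.metrics.acc > 0.6  # informative order-1 channel dominates


def test_leakage_canary(rng):
    """Corrupting a test-fold scan must not change training-fold selections."""
    ds = _toy_dataset(rng, n_subjects=30, signal=1.0)
    split = subject_level_folds(ds, k=5, seed=9)
    # pick a positive-class subject; give it a second, wildly mislabeled scan
    victim = next(s for s in ds.scans if s.label == "positive")
    garbage = _random_adj(rng, ds.scans[0].matrices[1].n_rois)
    extra = ScanRecord(matrices={1: garbage}, subject_id=victim.subject_id,
                       label="negative")
    ds2 = LabeledDataset(scans=ds.scans + (extra,))
    split2 = subject_level_folds(ds2, k=5, seed=9)
    assert split.assignments == split2.assignments  # same subjects, same split
    fold = split.assignments[victim.subject_id]
    y1, y2 = ds.labels(), ds2.labels()
    F1, F2 = ds.features(1), ds2.features(1)
    tr1 = split.train_indices(ds, fold)
    tr2 = split2.train_indices(ds2, fold)
    sel1 = ttest_select(F1[tr1], y1[tr1], 0.05)
    sel2 = ttest_select(F2[tr2], y2[tr2], 0.05)
    np.testing.assert_array_equal(sel1, sel2)
    # and the pooled experiment's training-fold feature counts agree there
    r1 = run_experiment(ds, orders=[1], p_grid=[0.05], k=5, seed=9)[(1, 0.05)]
    r2 = run_experiment(ds2, orders=[1], p_grid=[0.05], k=5, seed=9)[(1, 0.05)]
    assert r1.n_features_selected[fold] == r2.n_features_selected[fold]
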