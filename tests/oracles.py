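"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized implementation paths: the HMM
oracle enumerates every state path explicitly, and the alignment-score
oracles enumerate residue pairs / columns with plain loops.
"""

from __future__ import annotations

import numpy as np


def enumerate_paths(tr: dict, EM: np.ndarray, EI: np.ndarray):
    """All complete state paths emitting a fixed sequence.

    ``EM`` is (L, T) match emission log-probs for this sequence, ``EI``
    (T,) for insert/flank states.  Returns a list of
    ``(logprob, path)`` with paths as lists of ``(kind, index)``.
    """
    L, T = EM.shape
    results: list[tuple[float, list[tuple[str, int]]]] = []

    def go_M(i, j, lp, path):
        if j >= T:
            return
        at_M(i, j + 1, lp + EM[i, j], path + [("M", i)])

    def at_M(i, j, lp, path):
        if i == L - 1:
            at_E(j, lp, path)
        else:
            go_M(i + 1, j, lp + tr["mm"][i], path)
            go_I(i, j, lp + tr["mi"][i], path)
            at_D(i + 1, j, lp + tr["md"][i], path)

    def go_I(i, j, lp, path):
        if j >= T:
            return
        at_I(i, j + 1, lp + EI[j], path + [("I", i)])

    def at_I(i, j, lp, path):
        go_M(i + 1, j, lp + tr["im"][i], path)
        go_I(i, j, lp + tr["ii"][i], path)

    def at_D(i, j, lp, path):
        path = path + [("D", i)]
        if i == L - 1:
            at_E(j, lp, path)
        else:
            go_M(i + 1, j, lp + tr["dm"][i], path)
            at_D(i + 1, j, lp + tr["dd"][i], path)

    def at_E(j, lp, path):
        at_C(j, lp, path + [("E", 0)])

    def at_C(j, lp, path):
        if j < T:
            at_C(j + 1, lp + tr["cc"] + EI[j], path + [("C", 0)])
        else:
            results.append((lp + tr["ct"], path))

    def from_N(j, lp, path):
        if j < T:
            from_N(j + 1, lp + tr["nn"] + EI[j], path + [("N", 0)])
        from_B(j, lp + tr["nb"], path + [("B", 0)])

    def from_B(j, lp, path):
        go_M(0, j, lp + tr["bm"], path)
        at_D(0, j, lp + tr["bd"], path)

    from_N(0, 0.0, [])
    return results


def brute_force_loglik(tr, EM, EI) -> float:
    lps = np.array([lp for lp, _ in enumerate_paths(tr, EM, EI)])
    m = lps.max()
    return float(m + np.log(np.exp(lps - m).sum()))


def brute_force_viterbi(tr, EM, EI):
    results = enumerate_paths(tr, EM, EI)
    return max(lp for lp, _ in results)


def sp_score_bruteforce(pred, ref) -> float:
    """SP score by explicit enumeration of all reference residue pairs."""
    pred_cols = pred.column_residue_indices()
    ref_cols = ref.column_residue_indices()
    ids_ref = ref.identifiers
    ids_pred = pred.identifiers
    row_map = {ids_pred[i]: i for i in range(len(ids_pred))}

    def pair_set(cols, ids):
        pairs = set()
        for col in cols:
            members = sorted(col.items())
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    (ra, ia), (rb, ib) = members[x], members[y]
                    key = tuple(sorted([(ids[ra], ia), (ids[rb], ib)]))
                    pairs.add(key)
        return pairs

    ref_pairs = pair_set(ref_cols, ids_ref)
    pred_pairs = pair_set(pred_cols, ids_pred)
    if not ref_pairs:
        raise ValueError("reference has no residue pairs")
    return 100.0 * len(ref_pairs & pred_pairs) / len(ref_pairs)


def tc_score_bruteforce(pred, ref) -> float:
    """TC score by comparing columns as (row id, residue index) sets."""
    pred_cols = pred.column_residue_indices()
    ref_cols = ref.column_residue_indices()

    def as_sets(cols, ids):
        return [frozenset((ids[r], i) for r, i in col.items()) for col in cols]

    pred_sets = set(s for s in as_sets(pred_cols, pred.identifiers) if s)
    ref_sets = [s for s in as_sets(ref_cols, ref.identifiers) if s]
    if not ref_sets:
        raise ValueError("reference has no columns")
    hit = sum(1 for s in ref_sets if s in pred_sets)
    return 100.0 * hit / len(ref_sets)


def column_score_bruteforce(pred, ref) -> float:
    """Pair-weighted column score by explicit per-column counting."""
    pred_cols = pred.column_residue_indices()
    ref_cols = ref.column_residue_indices()

    def as_set(col, ids):
        return frozenset((ids[r], i) for r, i in col.items())

    pred_sets = set(
        as_set(c, pred.identifiers) for c in pred_cols if len(c) > 0
    )
    weights = []
    matched = []
    for col in ref_cols:
        m = len(col)
        pairs = m * (m - 1) // 2
        weights.append(pairs)
        matched.append(as_set(col, ref.identifiers) in pred_sets)
    total = sum(weights)
    if total == 0:
        raise ValueError("reference has zero residue pairs in columns")
    return 100.0 * sum(w for w, hit in zip(weights, matched) if hit) / total
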