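"""Reference-based alignment accuracy: SP, TC and weighted column scores.

All matching is by residue coordinates (row identifier, 0-based
ungapped residue index), never by characters, so repeated residues are
unambiguous.  Conventions pinned here: a pair of residues is aligned
iff they share a non-gap column; columns with fewer than two residues
contribute no pairs to SP or to the column-score weights but still
count as columns for TC; empty (all-gap) columns are ignored entirely.
"""

from __future__ import annotations

import numpy as np

from .msa_io import MultipleAlignment


def _check_comparable(pred: MultipleAlignment, ref: MultipleAlignment) -> dict[str, int]:
    """Validate id/content agreement; return ref row -> pred row map."""
    pred_index = {ident: k for k, ident in enumerate(pred.identifiers)}
    if set(pred.identifiers) != set(ref.identifiers):
        raise ValueError("prediction and reference hold different sequence sets")
    for r, ident in enumerate(ref.identifiers):
        if ref.degapped(r) != pred.degapped(pred_index[ident]):
            raise ValueError(f"row {ident!r} de-gaps to different sequences")
    return pred_index


def _residue_to_column(msa: MultipleAlignment) -> list[np.ndarray]:
    """Per row, array mapping ungapped residue index -> column index."""
    out = []
    for row in msa.rows:
        cols = [c for c, ch in enumerate(row) if ch not in "-."]
        out.append(np.asarray(cols, dtype=np.int64))
    return out


def sp_score(pred: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Percentage of reference residue pairs correctly co-aligned in pred."""
    pred_index = _check_comparable(pred, ref)
    pred_map = _residue_to_column(pred)
    total = correct = 0
    for col in ref.column_residue_indices():
        members = sorted(col.items())
        for x in range(len(members)):
            ra, ia = members[x]
            ca = pred_map[pred_index[ref.identifiers[ra]]][ia]
            for y in range(x + 1, len(members)):
                rb, ib = members[y]
                cb = pred_map[pred_index[ref.identifiers[rb]]][ib]
                total += 1
                correct += ca == cb
    if total == 0:
        raise ValueError("reference alignment has no residue pairs")
    return 100.0 * correct / total


def _column_matches(pred: MultipleAlignment, ref: MultipleAlignment):
    """For each non-empty ref column: (residue count, matched in pred)."""
    pred_index = _check_comparable(pred, ref)
    pred_map = _residue_to_column(pred)
    occupancy = np.zeros(max(pred.n_columns, 1), dtype=np.int64)
    for row in pred.rows:
        for c, ch in enumerate(row):
            if ch not in "-.":
                occupancy[c] += 1
    out = []
    for col in ref.column_residue_indices():
        if not col:
            continue
        target = None
        ok = True
        for r, i in col.items():
            c = pred_map[pred_index[ref.identifiers[r]]][i]
            if target is None:
                target = c
            elif c != target:
                ok = False
                break
        matched = ok and occupancy[target] == len(col)
        out.append((len(col), matched))
    if not out:
        raise ValueError("reference alignment has no columns")
    return out


def tc_score(pred: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Percentage of reference columns reproduced exactly in the prediction."""
    cols = _column_matches(pred, ref)
    return 100.0 * sum(m for _, m in cols) / len(cols)


def column_score(pred: MultipleAlignment, ref: MultipleAlignment) -> float:
    """TC weighted by each column's residue-pair count m(m-1)/2."""
    cols = _column_matches(pred, ref)
    weights = np.array([m * (m - 1) / 2 for m, _ in cols], dtype=float)
    total = weights.sum()
    if total == 0:
        raise ValueError("reference alignment has zero residue pairs in columns")
    hit = sum(w for w, (_, m) in zip(weights, cols) if m)
    return 100.0 * hit / total
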