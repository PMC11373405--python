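"""Decode a multiple alignment from a trained model.

Every sequence (and, when enabled, its compressed embeddings) is
aligned to the profile by Viterbi; residues emitted at match state
``M_i`` land in match column ``i`` (uppercase), deletions leave ``-``,
and insert/flank emissions are placed lowercase and left-justified in
insert-column blocks between match columns.  De-gapping any decoded
row reproduces the input sequence exactly.
"""

from __future__ import annotations

import numpy as np

from .embedding_emissions import background_log_density, embedding_emission_grid
from .msa_io import MultipleAlignment, Sequence
from .phmm_core import forward_backward, viterbi_decode, EncodedBatch
from .phmm_core import StatePath


def _extra_grids(ems, compressed):
    grid = embedding_emission_grid(ems, compressed)
    bg = background_log_density(ems, compressed)
    return grid[None, :, :], bg[None, :]


def paths_to_msa(seqs: list[Sequence], paths: list[StatePath], L_M: int) -> MultipleAlignment:
    """Assemble an alignment from per-sequence state paths.

    Insert blocks exist left of the core (flank N), between consecutive
    match columns, and right of the core (flank C); insertions are
    left-justified within their block and not aligned to each other.
    """
    if len(seqs) != len(paths):
        raise ValueError("sequence/path count mismatch")
    n_blocks = L_M + 1  # left flank, after-match 0..L_M-2, right flank
    match_cells = []
    insert_cells = []
    for seq, path in zip(seqs, paths):
        cells = [None] * L_M
        blocks: list[list[str]] = [[] for _ in range(n_blocks)]
        p = 0
        for kind, i in path.states:
            if kind == "N":
                blocks[0].append(seq.residues[p]); p += 1
            elif kind == "M":
                cells[i] = seq.residues[p]; p += 1
            elif kind == "I":
                blocks[i + 1].append(seq.residues[p]); p += 1
            elif kind == "C":
                blocks[L_M].append(seq.residues[p]); p += 1
        if p != len(seq):
            raise ValueError(
                f"path for {seq.identifier!r} emits {p} of {len(seq)} residues"
            )
        match_cells.append(cells)
        insert_cells.append(blocks)

    widths = [
        max(len(row[b]) for row in insert_cells) for b in range(n_blocks)
    ]
    rows = []
    flags: list[bool] = []
    build_flags = True
    for cells, blocks in zip(match_cells, insert_cells):
        out = []
        for b in range(n_blocks):
            ins = blocks[b]
            out.append("".join(ins).lower() + "-" * (widths[b] - len(ins)))
            if build_flags:
                flags.extend([False] * widths[b])
            if b < L_M:
                out.append(cells[b] if cells[b] is not None else "-")
                if build_flags:
                    flags.append(True)
        build_flags = False
        rows.append("".join(out))
    return MultipleAlignment([s.identifier for s in seqs], rows, flags)


def decode_msa(model, seqs: list[Sequence], cache=None) -> MultipleAlignment:
    """Viterbi-align every sequence to the trained model and stack rows.

    ``model`` is a :class:`~dphmm.training.TrainedModel`; ``cache`` must
    supply compressed embeddings when the model was trained with them.
    """
    use_emb = model.ems is not None
    if use_emb and cache is None:
        raise ValueError("model uses embeddings but no cache was provided")
    paths = []
    for seq in seqs:
        if use_emb:
            x = cache.get(seq.identifier)
            extra_m, extra_i = _extra_grids(model.ems, x)
            path, _ = viterbi_decode(model.hmm, seq, extra_m, extra_i)
        else:
            path, _ = viterbi_decode(model.hmm, seq)
        paths.append(path)
    msa = paths_to_msa(seqs, paths, model.hmm.length)
    for k, seq in enumerate(seqs):
        assert msa.degapped(k) == seq.residues
    return msa


def match_posteriors(model, seq: Sequence, cache=None) -> np.ndarray:
    """(L_M, L) posterior probability that match state i emitted residue j.

    Computed by forward–backward; the columns sum to at most 1 (the
    remainder is insert/flank/delete mass).  This is the probabilistic
    MSA output.
    """
    batch = EncodedBatch.from_sequences([seq])
    if model.ems is not None:
        if cache is None:
            raise ValueError("model uses embeddings but no cache was provided")
        x = cache.get(seq.identifier)
        extra_m, extra_i = _extra_grids(model.ems, x)
        _, grads = forward_backward(model.hmm, batch, extra_m, extra_i)
    else:
        _, grads = forward_backward(model.hmm, batch)
    return grads["bar_extra_match"][0]


def extract_reference_subalignment(msa: MultipleAlignment, reference_ids) -> MultipleAlignment:
    """Restrict rows to ``reference_ids`` and drop all-gap columns."""
    index = {ident: k for k, ident in enumerate(msa.identifiers)}
    missing = [i for i in reference_ids if i not in index]
    if missing:
        raise ValueError(f"unknown identifiers: {missing}")
    rows = [msa.rows[index[i]] for i in reference_ids]
    keep = [
        c
        for c in range(msa.n_columns)
        if any(r[c] not in "-." for r in rows)
    ]
    return MultipleAlignment(
        list(reference_ids),
        ["".join(r[c] for c in keep) for r in rows],
        [msa.match_columns[c] for c in keep],
    )
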