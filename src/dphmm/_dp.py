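"""Log-space dynamic-programming kernels for the profile topology.

State layout (model length ``L`` = number of match states):

* ``N`` — left flank insert; emits on its self-loop, exits to ``B``.
* ``B`` — silent begin; enters ``M_1`` or ``D_1``.
* ``M_i`` (i = 1..L) — match; ``M_i -> M_{i+1} | I_i | D_{i+1}``,
  ``M_L -> E`` with probability 1.
* ``I_i`` (i = 1..L-1) — insert between matches; ``I_i -> M_{i+1} | I_i``.
* ``D_i`` — silent delete chain; ``D_i -> M_{i+1} | D_{i+1}``,
  ``D_L -> E`` with probability 1.
* ``E`` — silent end, enters ``C`` with probability 1.
* ``C`` — right flank insert; emits on its self-loop, exits to
  termination.

All recurrences run in log space with log-sum-exp; the gradient of the
summed log-likelihood with respect to every emission cell and every
transition log-probability is obtained by an exact reverse sweep of the
same recurrences (the classical forward–backward expected counts).

Array conventions: ``EM[n, i, j]`` is the full emission log-probability
of residue ``j`` (0-based) at match state ``i`` for sequence ``n``
(amino-acid term plus any embedding term); ``EI[n, j]`` likewise for
the shared insert/flank states.  DP arrays are indexed by the number of
residues consumed, ``j = 0..T``.
"""

from __future__ import annotations

import numpy as np

#: Effective -infinity that stays NaN-free under add/subtract.
NEG = -1.0e30

_TRANS_SCALAR = ("nn", "nb", "cc", "ct", "bm", "bd")
_TRANS_VECTOR = ("mm", "mi", "md", "im", "ii", "dm", "dd")


def forward_pass(EM, EI, tr, lengths):
    """Run the forward algorithm over a padded batch.

    Returns ``(ll, state)`` where ``ll`` is the per-sequence
    log-likelihood and ``state`` caches the DP tables for the backward
    sweep.
    """
    n, L, T = EM.shape
    K = max(L - 1, 0)
    FN = np.full((n, T + 1), NEG)
    FB = np.full((n, T + 1), NEG)
    FM = np.full((n, T + 1, L), NEG)
    FI = np.full((n, T + 1, K), NEG)
    FD = np.full((n, T + 1, L), NEG)
    FE = np.full((n, T + 1), NEG)
    FC = np.full((n, T + 1), NEG)

    FN[:, 0] = 0.0
    FB[:, 0] = tr["nb"]
    FD[:, 0, 0] = FB[:, 0] + tr["bd"]
    for i in range(1, L):
        FD[:, 0, i] = FD[:, 0, i - 1] + tr["dd"][i - 1]
    FE[:, 0] = FD[:, 0, L - 1]
    FC[:, 0] = FE[:, 0]

    for j in range(1, T + 1):
        e_i = EI[:, j - 1]
        FN[:, j] = FN[:, j - 1] + tr["nn"] + e_i
        FB[:, j] = FN[:, j] + tr["nb"]
        FM[:, j, 0] = FB[:, j - 1] + tr["bm"] + EM[:, 0, j - 1]
        if L > 1:
            into = np.logaddexp(
                np.logaddexp(
                    FM[:, j - 1, : L - 1] + tr["mm"],
                    FI[:, j - 1, :] + tr["im"],
                ),
                FD[:, j - 1, : L - 1] + tr["dm"],
            )
            FM[:, j, 1:] = into + EM[:, 1:, j - 1]
            FI[:, j, :] = e_i[:, None] + np.logaddexp(
                FM[:, j - 1, : L - 1] + tr["mi"], FI[:, j - 1, :] + tr["ii"]
            )
        FD[:, j, 0] = FB[:, j] + tr["bd"]
        for i in range(1, L):
            FD[:, j, i] = np.logaddexp(
                FM[:, j, i - 1] + tr["md"][i - 1],
                FD[:, j, i - 1] + tr["dd"][i - 1],
            )
        FE[:, j] = np.logaddexp(FM[:, j, L - 1], FD[:, j, L - 1])
        FC[:, j] = np.logaddexp(FE[:, j], FC[:, j - 1] + tr["cc"] + e_i)

    ll = FC[np.arange(n), lengths] + tr["ct"]
    state = dict(FN=FN, FB=FB, FM=FM, FI=FI, FD=FD, FE=FE, FC=FC)
    return ll, state


def backward_pass(EM, EI, tr, lengths, state):
    """Exact gradient of ``sum(ll)`` by reverse sweep of the forward DP.

    Returns ``(bar_EM, bar_EI, tcounts)``: adjoints of the emission
    tables (the posterior state-occupancy weights) and expected usage
    counts of every transition log-probability.
    """
    n, L, T = EM.shape
    FN, FB, FM, FI, FD, FE, FC = (
        state[k] for k in ("FN", "FB", "FM", "FI", "FD", "FE", "FC")
    )
    bN = np.zeros((n, T + 1))
    bB = np.zeros((n, T + 1))
    bM = np.zeros_like(FM)
    bI = np.zeros_like(FI)
    bD = np.zeros_like(FD)
    bE = np.zeros((n, T + 1))
    bC = np.zeros((n, T + 1))
    bar_EM = np.zeros_like(EM)
    bar_EI = np.zeros_like(EI)
    tc = {k: 0.0 for k in _TRANS_SCALAR}
    tc.update({k: np.zeros(max(L - 1, 0)) for k in _TRANS_VECTOR})

    bC[np.arange(n), lengths] = 1.0
    tc["ct"] = float(n)

    for j in range(T, 0, -1):
        e_i = EI[:, j - 1]
        # FC[j] = lse(FE[j], FC[j-1] + cc + e_i)
        b = bC[:, j]
        w_loop = b * np.exp(FC[:, j - 1] + tr["cc"] + e_i - FC[:, j])
        bE[:, j] += b * np.exp(FE[:, j] - FC[:, j])
        bC[:, j - 1] += w_loop
        tc["cc"] += w_loop.sum()
        bar_EI[:, j - 1] += w_loop
        # FE[j] = lse(FM[j, L-1], FD[j, L-1])
        b = bE[:, j]
        bM[:, j, L - 1] += b * np.exp(FM[:, j, L - 1] - FE[:, j])
        bD[:, j, L - 1] += b * np.exp(FD[:, j, L - 1] - FE[:, j])
        # delete chain, descending i (same-j dependencies)
        for i in range(L - 1, 0, -1):
            b = bD[:, j, i]
            wm = b * np.exp(FM[:, j, i - 1] + tr["md"][i - 1] - FD[:, j, i])
            wd = b * np.exp(FD[:, j, i - 1] + tr["dd"][i - 1] - FD[:, j, i])
            bM[:, j, i - 1] += wm
            bD[:, j, i - 1] += wd
            tc["md"][i - 1] += wm.sum()
            tc["dd"][i - 1] += wd.sum()
        b = bD[:, j, 0]
        bB[:, j] += b
        tc["bd"] += b.sum()
        # FM[j, :]
        bar_EM[:, :, j - 1] += bM[:, j, :]
        b0 = bM[:, j, 0]
        bB[:, j - 1] += b0
        tc["bm"] += b0.sum()
        if L > 1:
            b = bM[:, j, 1:]
            into = FM[:, j, 1:] - EM[:, 1:, j - 1]
            wm = b * np.exp(FM[:, j - 1, : L - 1] + tr["mm"] - into)
            wi = b * np.exp(FI[:, j - 1, :] + tr["im"] - into)
            wd = b * np.exp(FD[:, j - 1, : L - 1] + tr["dm"] - into)
            bM[:, j - 1, : L - 1] += wm
            bI[:, j - 1, :] += wi
            bD[:, j - 1, : L - 1] += wd
            tc["mm"] += wm.sum(axis=0)
            tc["im"] += wi.sum(axis=0)
            tc["dm"] += wd.sum(axis=0)
            # FI[j, :]
            b = bI[:, j, :]
            bar_EI[:, j - 1] += b.sum(axis=1)
            into = FI[:, j, :] - e_i[:, None]
            wm = b * np.exp(FM[:, j - 1, : L - 1] + tr["mi"] - into)
            wi2 = b * np.exp(FI[:, j - 1, :] + tr["ii"] - into)
            bM[:, j - 1, : L - 1] += wm
            bI[:, j - 1, :] += wi2
            tc["mi"] += wm.sum(axis=0)
            tc["ii"] += wi2.sum(axis=0)
        # FB[j] = FN[j] + nb
        b = bB[:, j]
        bN[:, j] += b
        tc["nb"] += b.sum()
        # FN[j] = FN[j-1] + nn + e_i
        b = bN[:, j]
        bN[:, j - 1] += b
        tc["nn"] += b.sum()
        bar_EI[:, j - 1] += b

    # j = 0 wrap-up: FC[0] = FE[0] = FD[0, L-1] -> delete chain -> B -> N
    bE[:, 0] += bC[:, 0]
    bD[:, 0, L - 1] += bE[:, 0]
    for i in range(L - 1, 0, -1):
        b = bD[:, 0, i]
        bD[:, 0, i - 1] += b
        tc["dd"][i - 1] += b.sum()
    b = bD[:, 0, 0]
    bB[:, 0] += b
    tc["bd"] += b.sum()
    tc["nb"] += bB[:, 0].sum()

    return bar_EM, bar_EI, tc


def viterbi_single(EM, EI, tr):
    """Most probable path for one sequence.

    ``EM`` is ``(L, T)``, ``EI`` is ``(T,)``.  Ties prefer Match over
    Delete over Insert (candidates are ordered and replaced only on a
    strict improvement).  Returns ``(path, logprob)`` where ``path`` is
    a list of ``(kind, index)`` tuples (kinds ``N B M I D E C``; index
    is 0-based for core states, 0 otherwise) in generative order.
    """
    L, T = EM.shape
    K = max(L - 1, 0)
    VN = np.full(T + 1, NEG)
    VB = np.full(T + 1, NEG)
    VM = np.full((T + 1, L), NEG)
    VI = np.full((T + 1, K), NEG)
    VD = np.full((T + 1, L), NEG)
    VE = np.full(T + 1, NEG)
    VC = np.full(T + 1, NEG)
    # choices: M: 0=from B, 1=from M, 2=from D, 3=from I
    #          I: 0=from M, 1=from I;  D: 0=from B/M, 1=from D
    #          E: 0=from M_L, 1=from D_L;  C: 0=enter from E, 1=loop
    chM = np.zeros((T + 1, L), dtype=np.int8)
    chI = np.zeros((T + 1, K), dtype=np.int8)
    chD = np.zeros((T + 1, L), dtype=np.int8)
    chE = np.zeros(T + 1, dtype=np.int8)
    chC = np.zeros(T + 1, dtype=np.int8)

    def argbest(cands):
        """First index of the maximum among preference-ordered candidates."""
        best, k = cands[0], 0
        for idx in range(1, len(cands)):
            if cands[idx] > best:
                best, k = cands[idx], idx
        return best, k

    VN[0] = 0.0
    VB[0] = tr["nb"]
    VD[0, 0] = VB[0] + tr["bd"]
    for i in range(1, L):
        VD[0, i] = VD[0, i - 1] + tr["dd"][i - 1]
        chD[0, i] = 1
    VE[0], chE[0] = argbest([VM[0, L - 1], VD[0, L - 1]])
    VC[0] = VE[0]

    for j in range(1, T + 1):
        e_i = EI[j - 1]
        VN[j] = VN[j - 1] + tr["nn"] + e_i
        VB[j] = VN[j] + tr["nb"]
        VM[j, 0] = VB[j - 1] + tr["bm"] + EM[0, j - 1]
        chM[j, 0] = 0
        for i in range(1, L):
            best, k = argbest(
                [
                    VM[j - 1, i - 1] + tr["mm"][i - 1],
                    VD[j - 1, i - 1] + tr["dm"][i - 1],
                    VI[j - 1, i - 1] + tr["im"][i - 1],
                ]
            )
            VM[j, i] = best + EM[i, j - 1]
            chM[j, i] = (1, 2, 3)[k]
        for i in range(K):
            best, k = argbest(
                [VM[j - 1, i] + tr["mi"][i], VI[j - 1, i] + tr["ii"][i]]
            )
            VI[j, i] = best + e_i
            chI[j, i] = k
        VD[j, 0] = VB[j] + tr["bd"]
        chD[j, 0] = 0
        for i in range(1, L):
            best, k = argbest(
                [VM[j, i - 1] + tr["md"][i - 1], VD[j, i - 1] + tr["dd"][i - 1]]
            )
            VD[j, i] = best
            chD[j, i] = k
        VE[j], chE[j] = argbest([VM[j, L - 1], VD[j, L - 1]])
        best, k = argbest([VE[j], VC[j - 1] + tr["cc"] + e_i])
        VC[j] = best
        chC[j] = k

    logprob = VC[T] + tr["ct"]
    # traceback; one N/C entry per emitted flank residue, silent
    # traversals of the flanks leave no entry
    rev: list[tuple[str, int]] = []
    kind, i, j = "C", 0, T
    while True:
        if kind == "C":
            if chC[j] == 0:
                kind = "E"
            else:
                rev.append(("C", 0))
                j -= 1
        elif kind == "E":
            rev.append(("E", 0))
            kind, i = ("M", L - 1) if chE[j] == 0 else ("D", L - 1)
        elif kind == "M":
            rev.append(("M", i))
            c = chM[j, i]
            j -= 1
            if c == 0:
                kind = "B"
            elif c == 1:
                kind, i = "M", i - 1
            elif c == 2:
                kind, i = "D", i - 1
            else:
                kind, i = "I", i - 1
        elif kind == "I":
            rev.append(("I", i))
            c = chI[j, i]
            j -= 1
            kind = "M" if c == 0 else "I"
        elif kind == "D":
            rev.append(("D", i))
            if chD[j, i] == 0:
                kind = "B" if i == 0 else "M"
                i = i - 1
            else:
                kind, i = "D", i - 1
        elif kind == "B":
            rev.append(("B", 0))
            kind = "N"
        elif kind == "N":
            while j > 0:
                rev.append(("N", 0))
                j -= 1
            break
    path = rev[::-1]
    return path, float(logprob)
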