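"""Profile hidden Markov models: construction, scoring, sampling, logos.

The model is a classic match/insert/delete profile over the 20-letter
amino-acid alphabet.  Node ``j`` (0..L) groups the states ``M_j``, ``I_j``,
``D_j``; node 0 is the begin state (an emissionless ``M_0``) and node ``L+1``
the end state.  Seven transition probabilities leave each node:
``MM, MI, MD, IM, II, DM, DD`` (``I<->D`` adjacencies are not modelled, the
usual profile-HMM restriction).

All scores are log-odds in bits (log base 2) against a background null model
that emits each residue independently from ``bg``.  Insert emissions default
to the background, which makes inserts score-neutral.

Two alignment modes are supported:

* ``glocal`` — the whole sequence through the whole model (begin to end).
* ``local`` — free entry into any match state with probability ``1/L`` and
  free exit from any match state; flanking residues are unscored.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import (AA_INDEX, AMINO_ACIDS, GAP, UNKNOWN, Alignment,
                    SequenceRecord)

# transition indices
MM, MI, MD, IM, II, DM, DD = range(7)
_TRANS_NAMES = ["MM", "MI", "MD", "IM", "II", "DM", "DD"]

NEG_INF = float("-inf")

#: residue code used by iterative scanners to hard-mask already-called regions
MASK_CODE = 21


class ModelBuildError(ValueError):
    """Raised when an alignment cannot yield a valid profile."""


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray      # (L, 20)
    insert_emissions: np.ndarray     # (20,)
    transitions: np.ndarray          # (L+1, 7)
    background: np.ndarray           # (20,)
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        L = self.L
        if L < 1:
            raise ModelBuildError("profile must have at least one match state")
        if self.match_emissions.shape != (L, 20):
            raise ModelBuildError("match emission shape mismatch")
        if self.transitions.shape != (L + 1, 7):
            raise ModelBuildError("transition shape mismatch")
        for arr, what in ((self.match_emissions, "match emissions"),
                          (self.insert_emissions[None, :], "insert emissions"),
                          (self.background[None, :], "background")):
            if np.any(arr < -tol):
                raise ModelBuildError(f"negative {what}")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > tol):
                raise ModelBuildError(f"{what} rows do not sum to 1")
        t = self.transitions
        if np.any(t < -tol):
            raise ModelBuildError("negative transition probability")
        for j in range(L + 1):
            for sl, what in ((t[j, MM:MD + 1], "M"), (t[j, IM:II + 1], "I"),
                             (t[j, DM:DD + 1], "D")):
                if abs(sl.sum() - 1.0) > tol:
                    raise ModelBuildError(
                        f"outgoing {what} transitions at node {j} sum to {sl.sum()}")

    # cached log-space views -------------------------------------------------
    def _log_tables(self):
        key = "_log_cache"
        cached = self.__dict__.get(key)
        if cached is None:
            with np.errstate(divide="ignore"):
                lt = np.log2(self.transitions)
                lm = np.log2(self.match_emissions) - np.log2(self.background)
                li = np.log2(self.insert_emissions) - np.log2(self.background)
            # code 20 (unknown X) is score-neutral; code 21 is a hard mask
            # used by iterative domain scanning (no path may touch it)
            lm = np.concatenate([lm, np.zeros((self.L, 1)),
                                 np.full((self.L, 1), NEG_INF)], axis=1)
            li = np.concatenate([li, [0.0, NEG_INF]])
            cached = (lt, lm, li)
            self.__dict__[key] = cached
        return cached

    def information_content(self) -> np.ndarray:
        """Per-column relative entropy of match emissions vs background, bits."""
        e = self.match_emissions
        with np.errstate(divide="ignore", invalid="ignore"):
            term = e * (np.log2(e) - np.log2(self.background))
        term = np.where(e > 0, term, 0.0)
        return term.sum(axis=1)


def information_content(hmm: ProfileHMM) -> np.ndarray:
    return hmm.information_content()


# ---------------------------------------------------------------------------
# construction from an alignment
# ---------------------------------------------------------------------------

def position_based_weights(aln: Alignment) -> np.ndarray:
    """Henikoff position-based sequence weights, normalised to sum to n.

    Each column distributes weight 1 equally over the distinct residue types
    present (gaps excluded); a sequence's raw weight is the sum of its shares.
    """
    codes = aln.codes()
    n, L = codes.shape
    w = np.zeros(n)
    for c in range(L):
        col = codes[:, c]
        mask = col >= 0
        if not mask.any():
            continue
        vals, counts = np.unique(col[mask], return_counts=True)
        r = len(vals)
        share = {v: 1.0 / (r * k) for v, k in zip(vals, counts)}
        for i in np.flatnonzero(mask):
            w[i] += share[col[i]]
    if w.sum() <= 0:
        return np.ones(n)
    return w * (n / w.sum())


def _column_counts(codes_col: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted residue counts for one column; X spreads 1/20 to every residue."""
    counts = np.zeros(20)
    for i, c in enumerate(codes_col):
        if c < 0:
            continue
        if c == 20:
            counts += w[i] / 20.0
        else:
            counts[c] += w[i]
    return counts


def build_phmm(aln: Alignment,
               match_gap_threshold: float = 0.5,
               pseudocount_alpha: float = 1.0,
               weighting: str = "position_based",
               bg: str | np.ndarray = "uniform",
               name: str = "profile") -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Match columns are exactly those with (weighted) gap fraction strictly
    below ``match_gap_threshold``; ties become insert columns.  Emissions use
    background-proportional pseudocounts,
    ``e[j][a] = (c_ja + alpha * bg[a]) / (N_j + alpha)``; transitions use the
    same single-parameter smoothing with a uniform prior over the legal
    targets of each state.  Insert emissions are set to the background.
    """
    if pseudocount_alpha < 0:
        raise ValueError("pseudocount_alpha must be non-negative")
    if weighting not in ("none", "position_based"):
        raise ValueError(f"unknown weighting {weighting!r}")
    codes = aln.codes()
    n, L_all = codes.shape
    if weighting == "position_based":
        w = position_based_weights(aln)
    else:
        w = aln.effective_weights().astype(float)

    # column architecture uses the raw (unweighted) gap fraction so that the
    # match/insert layout does not depend on the weighting scheme
    gap_frac = (codes < 0).mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < match_gap_threshold)
    if match_cols.size == 0:
        raise ModelBuildError("alignment yields zero match columns")
    L = match_cols.size

    if isinstance(bg, str):
        if bg == "uniform":
            bgv = np.full(20, 1.0 / 20)
        elif bg == "empirical":
            tot = np.zeros(20)
            for c in range(L_all):
                tot += _column_counts(codes[:, c], w)
            if tot.sum() <= 0:
                raise ModelBuildError("cannot estimate empirical background")
            bgv = tot / tot.sum()
            bgv = np.clip(bgv, 1e-6, None)
            bgv /= bgv.sum()
        else:
            raise ValueError(f"unknown background spec {bg!r}")
    else:
        bgv = np.asarray(bg, dtype=float)
        bgv = bgv / bgv.sum()

    a = pseudocount_alpha
    emis = np.zeros((L, 20))
    for k, c in enumerate(match_cols):
        counts = _column_counts(codes[:, c], w)
        N = counts.sum()
        emis[k] = (counts + a * bgv) / (N + a) if (N + a) > 0 else bgv

    # ---- transition counts from per-sequence state paths -------------------
    tcounts = np.zeros((L + 1, 7))
    is_match = np.zeros(L_all, dtype=bool)
    is_match[match_cols] = True
    col_to_node = np.cumsum(is_match)          # alignment col -> node index after it
    for i in range(n):
        wi = w[i]
        row = codes[i]
        # state at each node 1..L: M (residue) or D (gap); node 0 is begin (M-like)
        node_state = ["M"]
        for c in match_cols:
            node_state.append("M" if row[c] >= 0 else "D")
        # inserted residues between node j and j+1
        ins = np.zeros(L + 1, dtype=int)
        for c in range(L_all):
            if not is_match[c] and row[c] >= 0:
                ins[col_to_node[c]] += 1
        for j in range(L + 1):
            s = node_state[j]
            nxt = node_state[j + 1] if j < L else "M"   # end behaves like M
            k = ins[j]
            if k > 0:
                # I<->D adjacencies are not modelled; a delete flanking an
                # insert run is collapsed onto the match path (rare, and
                # score-neutral since insert emissions equal the background).
                if s == "M":
                    tcounts[j, MI] += wi
                    tcounts[j, II] += wi * (k - 1)
                    tcounts[j, IM] += wi
                else:
                    tcounts[j, DM] += wi
            elif s == "M":
                tcounts[j, MM if nxt == "M" else MD] += wi
            else:
                tcounts[j, DM if nxt == "M" else DD] += wi

    trans = np.zeros((L + 1, 7))
    for j in range(L + 1):
        # legal outgoing sets: node L has no D_{L+1}; node 0 has no D_0
        m_targets = [MM, MI, MD] if j < L else [MM, MI]
        i_targets = [IM, II]
        d_targets = [DM, DD] if j < L else [DM]
        for idxs in (m_targets, i_targets, d_targets):
            m = len(idxs)
            c = tcounts[j, idxs]
            tot = c.sum()
            trans[j, idxs] = (c + a / m) / (tot + a) if (tot + a) > 0 else 1.0 / m
        if j == 0:
            trans[j, DM], trans[j, DD] = 1.0, 0.0   # D_0 does not exist

    hmm = ProfileHMM(name=name, match_emissions=emis, insert_emissions=bgv.copy(),
                     transitions=trans, background=bgv,
                     meta={"match_columns": [int(c) + 1 for c in match_cols]})
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# fast (vectorised) scoring
# ---------------------------------------------------------------------------

def _encode(seq: str | SequenceRecord) -> np.ndarray:
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if GAP in s:
        raise ValueError("cannot score a gapped sequence")
    return np.array([AA_INDEX[c] for c in s], dtype=np.int64)


def _insert_scan_max(curM: np.ndarray, li2: np.ndarray, t_mi: float, t_ii: float
                     ) -> np.ndarray:
    """Viterbi insert-state column: best over entry point and II run length."""
    n = curM.shape[0] - 1
    out = np.full(n + 1, NEG_INF)
    if t_mi == NEG_INF:
        return out
    if t_ii == NEG_INF:
        out[1:] = li2[1:] + curM[:-1] + t_mi
        return out
    idx = np.arange(n + 1, dtype=float)
    A = curM + t_mi - idx * t_ii
    run = np.maximum.accumulate(A)
    out[1:] = li2[1:] + (idx[1:] - 1.0) * t_ii + run[:-1]
    return out


def _insert_scan_sum(curM: np.ndarray, li2: np.ndarray, t_mi: float, t_ii: float
                     ) -> np.ndarray:
    n = curM.shape[0] - 1
    out = np.full(n + 1, NEG_INF)
    if t_mi == NEG_INF:
        return out
    if t_ii == NEG_INF:
        out[1:] = li2[1:] + curM[:-1] + t_mi
        return out
    idx = np.arange(n + 1, dtype=float)
    A = curM + t_mi - idx * t_ii
    with np.errstate(invalid="ignore"):
        run = np.logaddexp2.accumulate(A)
    out[1:] = li2[1:] + (idx[1:] - 1.0) * t_ii + run[:-1]
    return out


def _score_matrix_pass(hmm: ProfileHMM, codes: np.ndarray, mode: str,
                       summed: bool) -> tuple:
    """One DP sweep.  Returns (score, end_i, end_j) for Viterbi-style passes
    and (score, None, None) for forward passes."""
    lt, lm, li = hmm._log_tables()
    n = codes.shape[0]
    L = hmm.L
    lo = lm[:, codes]                   # (L, n)
    li2 = np.concatenate([[NEG_INF], li[codes]])   # 1-based over i
    scan = _insert_scan_sum if summed else _insert_scan_max
    comb3 = (lambda a, b, c: np.logaddexp2(np.logaddexp2(a, b), c)) if summed \
        else (lambda a, b, c: np.maximum(np.maximum(a, b), c))

    prevM = np.full(n + 1, NEG_INF)
    local = mode == "local"
    if not local:
        prevM[0] = 0.0                  # begin state, nothing emitted
    prevI = scan(prevM, li2, lt[0, MI], lt[0, II]) if not local \
        else np.full(n + 1, NEG_INF)
    prevD = np.full(n + 1, NEG_INF)
    entry = -math.log2(L) if local else NEG_INF

    best = NEG_INF
    best_i = best_j = -1
    endM = endI = endD = None
    for j in range(1, L + 1):
        tj = lt[j - 1]
        curM = np.full(n + 1, NEG_INF)
        cont = comb3(prevM[:-1] + tj[MM], prevI[:-1] + tj[IM], prevD[:-1] + tj[DM])
        if local:
            if summed:
                cont = np.logaddexp2(cont, entry)
            else:
                cont = np.maximum(cont, entry)
        curM[1:] = lo[j - 1, :] + cont
        if summed:
            curD = np.logaddexp2(prevM + tj[MD], prevD + tj[DD])
        else:
            curD = np.maximum(prevM + tj[MD], prevD + tj[DD])
        curI = scan(curM, li2, lt[j, MI], lt[j, II])
        if local:
            if summed:
                with np.errstate(invalid="ignore"):
                    col_best = np.logaddexp2(
                        best, np.logaddexp2.reduce(curM[1:])) if n else best
                best = col_best
            else:
                jmax = int(np.argmax(curM))
                if curM[jmax] > best:
                    best, best_i, best_j = float(curM[jmax]), jmax, j
        prevM, prevI, prevD = curM, curI, curD
    if local:
        return (best, best_i, best_j)
    tl = lt[L]
    if summed:
        sc = np.logaddexp2(np.logaddexp2(prevM[n] + tl[MM], prevI[n] + tl[IM]),
                           prevD[n] + tl[DM])
    else:
        sc = max(prevM[n] + tl[MM], prevI[n] + tl[IM], prevD[n] + tl[DM])
    return (float(sc), n, L)


def viterbi_score(hmm: ProfileHMM, seq: str | SequenceRecord,
                  mode: str = "local") -> float:
    """Best-path log-odds score in bits (no traceback)."""
    score, _, _ = _score_matrix_pass(hmm, _encode(seq), mode, summed=False)
    return score


def forward_score(hmm: ProfileHMM, seq: str | SequenceRecord,
                  mode: str = "local") -> float:
    """Log-odds of the summed path probability, in bits."""
    score, _, _ = _score_matrix_pass(hmm, _encode(seq), mode, summed=True)
    return float(score)


# ---------------------------------------------------------------------------
# Viterbi with traceback (reference implementation, exact tie-breaks)
# ---------------------------------------------------------------------------

@dataclass
class ViterbiPath:
    score: float
    #: list of (state, node, seq_pos) with 1-based seq_pos, None for deletes
    states: list[tuple[str, int, int | None]]
    seq_start: int
    seq_end: int

    def match_positions(self) -> dict[int, int | None]:
        """Model match column -> 1-based sequence position (None if deleted)."""
        out: dict[int, int | None] = {}
        for st, j, i in self.states:
            if st == "M":
                out[j] = i
            elif st == "D":
                out[j] = None
        return out


def viterbi_align(hmm: ProfileHMM, seq: str | SequenceRecord,
                  mode: str = "local") -> ViterbiPath:
    """Exact Viterbi with traceback.

    Tie-break on equal scores: prefer M over D over I predecessors, then the
    lower entry column in local mode.
    """
    codes = _encode(seq)
    lt, lm, li = hmm._log_tables()
    n, L = codes.shape[0], hmm.L
    local = mode == "local"
    entry = -math.log2(L)

    VM = np.full((n + 1, L + 1), NEG_INF)
    VI = np.full((n + 1, L + 1), NEG_INF)
    VD = np.full((n + 1, L + 1), NEG_INF)
    PM = np.zeros((n + 1, L + 1), dtype=np.int8)   # 0:M 1:D 2:I 3:entry/begin
    PI = np.zeros((n + 1, L + 1), dtype=np.int8)   # 0: from M, 2: from I
    PD = np.zeros((n + 1, L + 1), dtype=np.int8)   # 0: from M, 1: from D

    beginM = np.full(n + 1, NEG_INF)
    beginM[0] = 0.0 if not local else NEG_INF
    # I_0 (glocal only)
    if not local:
        for i in range(1, n + 1):
            cand_m = beginM[i - 1] + lt[0, MI]
            cand_i = VI[i - 1, 0] + lt[0, II]
            if cand_m >= cand_i:
                VI[i, 0], PI[i, 0] = li[codes[i - 1]] + cand_m, 0
            else:
                VI[i, 0], PI[i, 0] = li[codes[i - 1]] + cand_i, 2

    for j in range(1, L + 1):
        tj = lt[j - 1]
        for i in range(0, n + 1):
            # D_j (no emission)
            pm = (beginM[i] if j == 1 else VM[i, j - 1]) + tj[MD]
            pd = VD[i, j - 1] + tj[DD]
            if pm >= pd:
                VD[i, j], PD[i, j] = pm, 0
            else:
                VD[i, j], PD[i, j] = pd, 1
            if i == 0:
                continue
            # M_j
            prevm = beginM[i - 1] if j == 1 else VM[i - 1, j - 1]
            cands = [(prevm + tj[MM], 3 if j == 1 and not local else 0),
                     (VD[i - 1, j - 1] + tj[DM], 1),
                     (VI[i - 1, j - 1] + tj[IM], 2)]
            if local:
                cands.append((entry, 3))
            best, ptr = NEG_INF, 3
            for val, p in cands:
                if val > best + 1e-12:
                    best, ptr = val, p
            VM[i, j] = lm[j - 1, codes[i - 1]] + best
            PM[i, j] = ptr
            # I_j
            cand_m = VM[i - 1, j] + lt[j, MI]
            cand_i = VI[i - 1, j] + lt[j, II]
            if cand_m >= cand_i:
                VI[i, j], PI[i, j] = li[codes[i - 1]] + cand_m, 0
            else:
                VI[i, j], PI[i, j] = li[codes[i - 1]] + cand_i, 2

    # termination
    if local:
        best, bi, bj = NEG_INF, -1, -1
        for j in range(1, L + 1):
            for i in range(1, n + 1):
                if VM[i, j] > best + 1e-12:
                    best, bi, bj = VM[i, j], i, j
        if bi < 0:
            raise ValueError("no valid local alignment (empty model/sequence?)")
        state, i, j = "M", bi, bj
    else:
        tl = lt[L]
        opts = [("M", VM[n, L] + tl[MM]), ("D", VD[n, L] + tl[DM]),
                ("I", VI[n, L] + tl[IM])]
        state, best = max(opts, key=lambda kv: (kv[1], kv[0] == "M", kv[0] == "D"))
        i, j = n, L

    # traceback
    states: list[tuple[str, int, int | None]] = []
    while True:
        if state == "M":
            states.append(("M", j, i))
            ptr = PM[i, j]
            i, j = i - 1, j - 1
            if ptr == 3 or (j == 0 and ptr == 0):
                break
            state = {0: "M", 1: "D", 2: "I"}[ptr]
        elif state == "D":
            states.append(("D", j, None))
            ptr = PD[i, j]
            j = j - 1
            if j == 0:
                break
            state = {0: "M", 1: "D"}[ptr]
        else:
            states.append(("I", j, i))
            ptr = PI[i, j]
            i = i - 1
            if ptr == 0 and j == 0:   # came from begin via MI at node 0
                break
            state = {0: "M", 2: "I"}[ptr]
    states.reverse()
    emitted = [p for _, _, p in states if p is not None]
    seq_start = emitted[0] if emitted else 1
    seq_end = emitted[-1] if emitted else 0
    return ViterbiPath(score=float(best), states=states,
                       seq_start=seq_start, seq_end=seq_end)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_sequence(hmm: ProfileHMM, rng: np.random.Generator
                    ) -> tuple[SequenceRecord, list[tuple[str, int, int | None]]]:
    """Emit one sequence from the model (glocal walk begin -> end)."""
    t = hmm.transitions
    residues: list[str] = []
    states: list[tuple[str, int, int | None]] = []
    state, j = "M", 0       # begin
    L = hmm.L
    while True:
        if state == "M":
            probs = t[j, [MM, MI, MD]]
        elif state == "I":
            probs = np.array([t[j, IM], t[j, II], 0.0])
        else:
            probs = np.array([t[j, DM], 0.0, t[j, DD]])
        probs = probs / probs.sum()
        choice = rng.choice(3, p=probs)
        if choice == 1:          # -> I_j
            state = "I"
            a = rng.choice(20, p=hmm.insert_emissions)
            residues.append(AMINO_ACIDS[a])
            states.append(("I", j, len(residues)))
            continue
        j += 1
        if j > L:
            break
        if choice == 0:
            state = "M"
            a = rng.choice(20, p=hmm.match_emissions[j - 1])
            residues.append(AMINO_ACIDS[a])
            states.append(("M", j, len(residues)))
        else:
            state = "D"
            states.append(("D", j, None))
    if not residues:
        residues = [AMINO_ACIDS[rng.choice(20, p=hmm.background)]]
    return SequenceRecord("sample", "".join(residues)), states


def sample_alignment(hmm: ProfileHMM, n: int, seed: int) -> Alignment:
    """Sample ``n`` sequences and return their match-state alignment
    (one column per model column; inserts discarded, deletes as gaps)."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n):
        rec, states = sample_sequence(hmm, rng)
        row = ["-"] * hmm.L
        for st, j, pos in states:
            if st == "M":
                row[j - 1] = rec.residues[pos - 1]
        rows.append(SequenceRecord(f"s{k:05d}", "".join(row)))
    return Alignment(rows)


# ---------------------------------------------------------------------------
# logos
# ---------------------------------------------------------------------------

@dataclass
class LogoTable:
    """Information-content logo: column heights in bits, letters stacked in
    proportion to their emission probability (Schneider-style)."""

    heights: np.ndarray                       # (L,)
    letters: list[list[tuple[str, float]]]    # per column, descending

    @classmethod
    def from_hmm(cls, hmm: ProfileHMM, min_letter: float = 1e-4) -> "LogoTable":
        ic = hmm.information_content()
        letters = []
        for j in range(hmm.L):
            stack = [(AMINO_ACIDS[a], float(hmm.match_emissions[j, a] * ic[j]))
                     for a in range(20)]
            stack = [(c, h) for c, h in stack if h > min_letter]
            stack.sort(key=lambda ch: (-ch[1], ch[0]))
            letters.append(stack)
        return cls(heights=ic, letters=letters)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# column\theight_bits\tletters\n")
            for j, (h, stack) in enumerate(zip(self.heights, self.letters), start=1):
                spec = ",".join(f"{c}:{v:.6f}" for c, v in stack)
                fh.write(f"{j}\t{h:.6f}\t{spec}\n")


def render_logo_svg(table: LogoTable, path: str | Path) -> None:
    """Render a logo as SVG with matplotlib glyphs scaled to letter heights."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    L = len(table.letters)
    fig, ax = plt.subplots(figsize=(max(4, L * 0.28), 2.6))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    cmap = {"K": "#1f78b4", "R": "#1f78b4", "H": "#1f78b4",
            "D": "#e31a1c", "E": "#e31a1c",
            "C": "#ff7f00", "G": "#33a02c", "S": "#33a02c", "T": "#33a02c",
            "P": "#6a3d9a"}
    for j, stack in enumerate(table.letters):
        y = 0.0
        for c, h in sorted(stack, key=lambda ch: ch[1]):
            tp = TextPath((0, 0), c, size=1.0, prop=fp)
            bb = tp.get_extents()
            sx = 0.9 / bb.width if bb.width else 1.0
            sy = h / bb.height if bb.height else 1.0
            tr = (Affine2D().translate(-bb.x0, -bb.y0).scale(sx, sy)
                  .translate(j + 0.05, y))
            ax.add_patch(PathPatch(tr.transform_path(tp),
                                   color=cmap.get(c, "#444444"), lw=0))
            y += h
    ax.set_xlim(0, L)
    ax.set_ylim(0, max(4.5, float(table.heights.max(initial=0.0)) + 0.2))
    ax.set_xlabel("model column")
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(0.5, L, max(1, L // 20)))
    ax.set_xticklabels(np.arange(1, L + 1, max(1, L // 20)))
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def logo_export(hmm: ProfileHMM, path: str | Path,
                svg_path: str | Path | None = None) -> LogoTable:
    """Write the logo table as TSV (and optionally an SVG rendering)."""
    table = LogoTable.from_hmm(hmm)
    table.to_tsv(path)
    if svg_path is not None:
        render_logo_svg(table, svg_path)
    return table


# ---------------------------------------------------------------------------
# serialization (taumap profile TSV; floats via repr -> exact round-trip)
# ---------------------------------------------------------------------------

def write_model(hmm: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# taumap-profile v1\n")
        fh.write(f"name\t{hmm.name}\n")
        fh.write(f"L\t{hmm.L}\n")
        fh.write(f"alphabet\t{AMINO_ACIDS}\n")
        fh.write("bg\t" + "\t".join(repr(float(v)) for v in hmm.background) + "\n")
        fh.write("insert\t" + "\t".join(repr(float(v))
                                        for v in hmm.insert_emissions) + "\n")
        for k, v in hmm.meta.items():
            if k.startswith("_"):
                continue
            fh.write(f"meta:{k}\t{v}\n")
        for j in range(hmm.L + 1):
            fh.write(f"T\t{j}\t" + "\t".join(repr(float(v))
                                             for v in hmm.transitions[j]) + "\n")
        for j in range(1, hmm.L + 1):
            fh.write(f"E\t{j}\t" + "\t".join(repr(float(v))
                                             for v in hmm.match_emissions[j - 1]) + "\n")


def read_model(path: str | Path) -> ProfileHMM:
    name, L = "profile", None
    bg = ins = None
    meta: dict = {}
    trans = {}
    emis = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            key = parts[0]
            if key == "name":
                name = parts[1]
            elif key == "L":
                L = int(parts[1])
            elif key == "alphabet":
                if parts[1] != AMINO_ACIDS:
                    raise ValueError("unsupported alphabet in model file")
            elif key == "bg":
                bg = np.array([float(v) for v in parts[1:]])
            elif key == "insert":
                ins = np.array([float(v) for v in parts[1:]])
            elif key.startswith("meta:"):
                meta[key[5:]] = parts[1]
            elif key == "T":
                trans[int(parts[1])] = [float(v) for v in parts[2:]]
            elif key == "E":
                emis[int(parts[1])] = [float(v) for v in parts[2:]]
    if L is None or bg is None or ins is None or len(trans) != L + 1 or len(emis) != L:
        raise ValueError(f"incomplete model file {path}")
    hmm = ProfileHMM(
        name=name,
        match_emissions=np.array([emis[j] for j in range(1, L + 1)]),
        insert_emissions=ins,
        transitions=np.array([trans[j] for j in range(L + 1)]),
        background=bg, meta=meta)
    hmm.validate()
    return hmm


def read_hmmer3(path: str | Path) -> ProfileHMM:
    """Best-effort import of a HMMER3 ASCII ``.hmm`` file.

    Reads match emissions, insert emissions and the seven node transitions
    (HMMER stores them as negative natural logs; ``*`` means probability 0).
    The background is approximated by the file's ``COMPO`` average
    composition.  Only single-model files are supported.
    """
    def conv(tok: str) -> float:
        return 0.0 if tok == "*" else math.exp(-float(tok))

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise ValueError("not a HMMER3 ASCII file")
    name = "hmmer_import"
    i = 0
    while not lines[i].startswith("HMM "):
        if lines[i].startswith("NAME"):
            name = lines[i].split(None, 1)[1].strip()
        if lines[i].startswith("LENG"):
            L = int(lines[i].split()[1])
        i += 1
    alpha_order = lines[i].split()[1:]
    i += 2  # skip transition-header line
    toks = lines[i].split()
    if toks[0] != "COMPO":
        raise ValueError("missing COMPO line")
    compo = np.array([conv(t) for t in toks[1:21]])
    i += 1
    insert = np.array([conv(t) for t in lines[i].split()[:20]])
    i += 1
    t0 = np.array([conv(t) for t in lines[i].split()[:7]])
    i += 1
    emis = np.zeros((L, 20))
    trans = np.zeros((L + 1, 7))
    trans[0] = t0
    for j in range(1, L + 1):
        toks = lines[i].split()
        if int(toks[0]) != j:
            raise ValueError(f"unexpected node line at {lines[i][:30]!r}")
        row = np.array([conv(t) for t in toks[1:21]])
        i += 2  # skip insert-emission line (taken as shared from node 0)
        trans[j] = np.array([conv(t) for t in lines[i].split()[:7]])
        i += 1
        emis[j - 1] = row
    # reorder emissions from the file's alphabet to ours
    order = [alpha_order.index(a) for a in AMINO_ACIDS]
    emis = emis[:, order]
    insert = insert[order]
    compo = compo[order]
    bg = compo / compo.sum()
    emis = emis / emis.sum(axis=1, keepdims=True)
    insert = insert / insert.sum()
    # repair structural edge rows so validation passes
    trans[L, MD] = 0.0
    trans[L, DD] = 0.0
    for j in range(L + 1):
        for sl in ((MM, MI, MD), (IM, II), (DM, DD)):
            s = trans[j, list(sl)].sum()
            if s > 0:
                trans[j, list(sl)] /= s
            else:
                trans[j, sl[0]] = 1.0
    hmm = ProfileHMM(name=name, match_emissions=emis, insert_emissions=insert,
                     transitions=trans, background=bg,
                     meta={"source": "hmmer3"})
    hmm.validate()
    return hmm
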