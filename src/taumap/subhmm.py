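"""SubHMM segmentation and profile-profile matching across clades.

A clade profile is cut into "subHMMs" — maximal runs of high-information
columns — each treated as a standalone motif model.  Motifs are then matched
against the profiles of other clades with a local profile-profile alignment
whose column score is the background-normalised co-emission log-odds

    s(i, j) = log2( sum_a e1[i][a] * e2[j][a] / bg[a] ) - delta

(``delta`` is a per-column shift that keeps the expected score of unrelated
columns negative, a requirement for meaningful local alignment).  The
alignment score maps to a match probability through a logistic curve whose
constants were calibrated once on simulated clade families and are fixed in
:data:`PP_CALIBRATION`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .phmm import DD, DM, IM, II, MD, MI, MM, ProfileHMM

#: logistic calibration of match probability vs alignment score (bits);
#: fitted once on simulated clade profiles (see docs/methods.md)
PP_CALIBRATION = {"shift": 1.0, "s0": 10.0, "tau": 1.5}
DEFAULT_GAP_OPEN = 8.0
DEFAULT_GAP_EXTEND = 2.0

_ROMAN = (("M", 1000), ("CM", 900), ("D", 500), ("CD", 400), ("C", 100),
          ("XC", 90), ("L", 50), ("XL", 40), ("X", 10), ("IX", 9),
          ("V", 5), ("IV", 4), ("I", 1))


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for sym, val in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class SubHMM:
    parent: str
    start_col: int        # 1-based inclusive columns of the parent profile
    end_col: int
    model: ProfileHMM
    label: str            # Roman numeral in left-to-right discovery order

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1


@dataclass
class ProfileMatch:
    sub_label: str
    target_name: str
    target_start: int     # 1-based columns of the target profile
    target_end: int
    score: float          # bits
    probability: float
    present: bool | None = None


def slice_profile(hmm: ProfileHMM, start: int, end: int) -> ProfileHMM:
    """A standalone profile over parent columns start..end (1-based incl.).

    Internal transitions are inherited; begin mass enters at the slice start
    and exit transitions at the last node fold the truncated delete path into
    the end state.
    """
    if not 1 <= start <= end <= hmm.L:
        raise ValueError(f"slice {start}..{end} outside 1..{hmm.L}")
    Ls = end - start + 1
    emis = hmm.match_emissions[start - 1:end].copy()
    trans = np.zeros((Ls + 1, 7))
    trans[0] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]        # fresh begin
    trans[1:] = hmm.transitions[start:end + 1]
    # renormalise the final node: no M/D states beyond the slice
    trans[Ls, MM] += trans[Ls, MD]
    trans[Ls, MD] = 0.0
    trans[Ls, DM] += trans[Ls, DD]
    trans[Ls, DD] = 0.0
    sub = ProfileHMM(name=f"{hmm.name}[{start}-{end}]",
                     match_emissions=emis,
                     insert_emissions=hmm.insert_emissions.copy(),
                     transitions=trans,
                     background=hmm.background.copy(),
                     meta={"parent": hmm.name, "start_col": str(start),
                           "end_col": str(end)})
    sub.validate()
    return sub


def segment_subhmms(hmm: ProfileHMM, ic_min: float = 1.0, min_len: int = 6,
                    merge_gap: int = 3) -> list[SubHMM]:
    """Cut a profile into conserved motif blocks.

    Columns with information content >= ``ic_min`` bits are marked; maximal
    marked runs separated by at most ``merge_gap`` unmarked columns merge;
    runs shorter than ``min_len`` are dropped.  Surviving runs become
    subHMMs labelled I, II, ... left to right.
    """
    ic = hmm.information_content()
    marked = ic >= ic_min
    runs: list[list[int]] = []
    j = 0
    while j < hmm.L:
        if marked[j]:
            k = j
            while k + 1 < hmm.L and marked[k + 1]:
                k += 1
            if runs and j - (runs[-1][1] + 1) <= merge_gap:
                runs[-1][1] = k
            else:
                runs.append([j, k])
            j = k + 1
        else:
            j += 1
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_len]
    return [SubHMM(parent=hmm.name, start_col=a + 1, end_col=b + 1,
                   model=slice_profile(hmm, a + 1, b + 1), label=roman(i + 1))
            for i, (a, b) in enumerate(runs)]


def _column_scores(sub_e: np.ndarray, tgt_e: np.ndarray, bg: np.ndarray,
                   shift: float) -> np.ndarray:
    co = sub_e @ (tgt_e / bg).T
    with np.errstate(divide="ignore"):
        return np.log2(np.maximum(co, 1e-300)) - shift


def profile_profile_align(sub: SubHMM, target: ProfileHMM,
                          gap_open: float = DEFAULT_GAP_OPEN,
                          gap_extend: float = DEFAULT_GAP_EXTEND,
                          calibration: dict | None = None) -> ProfileMatch:
    """Best local alignment of subHMM columns to target profile columns.

    Smith-Waterman with affine column-gap penalties over the co-emission
    score matrix; an empty alignment scores 0.  The probability is the
    logistic transform ``1 / (1 + exp(-(score - s0)/tau))``.
    """
    cal = dict(PP_CALIBRATION)
    if calibration:
        cal.update(calibration)
    S = _column_scores(sub.model.match_emissions, target.match_emissions,
                       sub.model.background, cal["shift"])
    m, n = S.shape
    NEG = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)   # gap in sub (consume target column)
    F = np.full((m + 1, n + 1), NEG)   # gap in target
    startH = np.zeros((m + 1, n + 1, 2), dtype=int)
    startE = np.zeros((m + 1, n + 1, 2), dtype=int)
    startF = np.zeros((m + 1, n + 1, 2), dtype=int)
    best, bi, bj = 0.0, 0, 0
    best_start = (1, 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] - gap_open
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j], startE[i, j] = eo, startH[i, j - 1]
            else:
                E[i, j], startE[i, j] = ee, startE[i, j - 1]
            fo = H[i - 1, j] - gap_open
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j], startF[i, j] = fo, startH[i - 1, j]
            else:
                F[i, j], startF[i, j] = fe, startF[i - 1, j]
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            dstart = startH[i - 1, j - 1] if H[i - 1, j - 1] > 0 else (i, j)
            h, hs = diag, dstart
            if E[i, j] > h:
                h, hs = E[i, j], startE[i, j]
            if F[i, j] > h:
                h, hs = F[i, j], startF[i, j]
            if h <= 0:
                h, hs = 0.0, (i, j)
            H[i, j] = h
            startH[i, j] = hs
            if h > best:
                best, bi, bj = float(h), i, j
                best_start = tuple(hs)
    if best > 0:
        t_start, t_end = int(best_start[1]), bj
    else:
        t_start, t_end = 1, 0      # empty alignment
    prob = 1.0 / (1.0 + math.exp(-(best - cal["s0"]) / cal["tau"]))
    return ProfileMatch(sub_label=sub.label, target_name=target.name,
                        target_start=t_start, target_end=t_end,
                        score=best, probability=prob)


@dataclass
class PresenceMatrix:
    subs: list[SubHMM]
    targets: list[str]
    matches: dict[tuple[str, str], ProfileMatch]
    p_min: float
    ref_map: dict[int, int] | None = None    # parent column -> reference residue

    def present(self, sub_label: str, target_name: str) -> bool:
        return bool(self.matches[(sub_label, target_name)].present)

    def ref_span(self, sub: SubHMM) -> tuple[int, int]:
        if not self.ref_map:
            return sub.start_col, sub.end_col
        cols = [self.ref_map[c] for c in range(sub.start_col, sub.end_col + 1)
                if self.ref_map.get(c) is not None]
        if not cols:
            return 0, 0
        return min(cols), max(cols)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# sub_label\tparent_start\tparent_end\tref_start\tref_end"
                     "\ttarget\tscore_bits\tprobability\tpresent"
                     "\ttarget_start\ttarget_end\n")
            for sub in self.subs:
                r0, r1 = self.ref_span(sub)
                for t in self.targets:
                    match = self.matches[(sub.label, t)]
                    fh.write(f"{sub.label}\t{sub.start_col}\t{sub.end_col}"
                             f"\t{r0}\t{r1}\t{t}\t{match.score:.4f}"
                             f"\t{match.probability:.6f}"
                             f"\t{str(bool(match.present)).lower()}"
                             f"\t{match.target_start}\t{match.target_end}\n")


def motif_presence_matrix(subs: Sequence[SubHMM], targets: Sequence[ProfileHMM],
                          p_min: float = 0.8,
                          ref_map: dict[int, int] | None = None
                          ) -> PresenceMatrix:
    """Match every subHMM against every target profile.

    ``ref_map`` (parent column -> 1-based residue of a reference sequence,
    e.g. from a Viterbi alignment of the reference against the parent)
    projects motif spans onto reference coordinates for ribbon plots.
    """
    if not subs or not targets:
        raise ValueError("need at least one subHMM and one target profile")
    matches = {}
    for sub in subs:
        for t in targets:
            match = profile_profile_align(sub, t)
            match.present = match.probability >= p_min
            matches[(sub.label, t.name)] = match
    return PresenceMatrix(subs=list(subs), targets=[t.name for t in targets],
                          matches=matches, p_min=p_min, ref_map=ref_map)


def reference_column_map(parent: ProfileHMM, ref_residues: str) -> dict[int, int]:
    """Map parent profile columns to 1-based positions of a reference sequence
    via a glocal Viterbi alignment."""
    from .phmm import viterbi_align
    path = viterbi_align(parent, ref_residues, mode="glocal")
    return path.match_positions()
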