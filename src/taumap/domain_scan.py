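"""Multi-class domain scanning and tandem-repeat architecture calling.

Each microtubule-binding domain (MTBD) class is represented by a profile HMM
(e.g. ``MAPT_R2``).  A protein is scanned with every class model; candidate
local hits are pooled, selected greedily by bit score under an overlap rule,
and each accepted hit is re-scored by all models to assign its class, the
runner-up class and the classification margin.  Ordered hits compact into an
architecture string with run-length notation for tandem expansions, e.g.
``R1-R2x4-R3-R4`` for the icefish-like four-fold duplication of repeat 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phmm import MASK_CODE, ProfileHMM, _encode, _score_matrix_pass, viterbi_align
from .seqio import GAP, SequenceRecord

#: model columns holding the KxGS core motif, 1-based, inclusive
DEFAULT_CORE_COLUMNS = (15, 18)
#: the variable core position ('x' of KxGS): Cys in repeats 2-3, Ile/Val in 1 and 4
DEFAULT_VARIABLE_CORE = 16

#: a hit may overlap an accepted hit by at most this fraction of the shorter one
OVERLAP_TOLERANCE = 0.10
#: window padding (residues) when re-scoring an accepted hit with all models
RESCORE_PAD = 5
#: a candidate must align at least this fraction of the model's match columns;
#: guards against few-residue chance matches that clear the bit threshold
MIN_MODEL_COVERAGE = 0.5


@dataclass
class DomainHit:
    seq_id: str
    class_name: str
    start: int            # 1-based inclusive
    end: int
    score: float          # bits, winning class on the re-scored window
    runner_up_class: str | None = None
    margin: float = 0.0
    core_motif: str = ""
    cys_flag: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad hit coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def display_class(self) -> str:
        """Repeat label without the paralog prefix (MAPT_R2 -> R2)."""
        return self.class_name.split("_")[-1]


@dataclass
class Architecture:
    seq_id: str
    hits: list[DomainHit]
    string: str
    expansions: list[tuple[str, int]]


def _match_columns(hmm: ProfileHMM) -> list[int] | None:
    mc = hmm.meta.get("match_columns")
    if mc is None:
        return None
    if isinstance(mc, str):
        mc = [int(tok) for tok in mc.strip("[] ").replace(",", " ").split()]
    return list(mc)


def annotate_core_columns(hmm: ProfileHMM,
                          core_columns: tuple[int, int] = DEFAULT_CORE_COLUMNS,
                          variable_core: int = DEFAULT_VARIABLE_CORE) -> ProfileHMM:
    """Record where the KxGS core sits in *model* coordinates.

    ``core_columns``/``variable_core`` are given in the training alignment's
    frame (the 33-column repeat frame); models built from classes with the
    position-12 deletion lose that column, shifting everything after it by
    one.  The build's match-column map translates the coordinates.
    """
    mc = _match_columns(hmm)

    def to_model(col: int) -> int:
        if mc is None:
            return col
        return sum(1 for c in mc if c <= col)

    lo, hi = (to_model(c) for c in core_columns)
    var = to_model(variable_core)
    hmm.meta["core_columns"] = f"{lo}-{hi}"
    hmm.meta["variable_core"] = str(var)
    return hmm


def _model_core_columns(hmm: ProfileHMM) -> tuple[int, int, int]:
    lo, hi = DEFAULT_CORE_COLUMNS
    var = DEFAULT_VARIABLE_CORE
    if "core_columns" in hmm.meta:
        lo, hi = (int(v) for v in str(hmm.meta["core_columns"]).split("-"))
    if "variable_core" in hmm.meta:
        var = int(hmm.meta["variable_core"])
    return lo, hi, var


def _local_hits_one_model(hmm: ProfileHMM, codes: np.ndarray, min_score: float,
                          max_hits: int = 50) -> list[tuple[float, int, int]]:
    """Iteratively find non-overlapping local hits of one model by masking.

    Returns (score, start, end) triples, 1-based coordinates.
    """
    work = codes.copy()
    n = work.shape[0]
    out = []
    for _ in range(max_hits):
        score, end_i, _end_j = _score_matrix_pass(hmm, work, "local", summed=False)
        if score < min_score or end_i < 0:
            break
        # exact boundaries from a traceback restricted to a window around the end
        w0 = max(0, end_i - (hmm.L + 16))
        window = work[w0:end_i]
        path = viterbi_align(hmm, _codes_to_str(window), mode="local")
        start = w0 + path.seq_start
        end = w0 + path.seq_end
        matched = sum(1 for st, _, _ in path.states if st == "M")
        if matched >= MIN_MODEL_COVERAGE * hmm.L:
            out.append((float(score), start, end))
        work[start - 1:end] = MASK_CODE     # mask either way to make progress
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    from .seqio import AMINO_ACIDS, UNKNOWN
    table = AMINO_ACIDS + UNKNOWN + UNKNOWN   # mask re-encodes as X for traceback
    return "".join(table[c] for c in codes)


def scan_domains(seq: SequenceRecord, models: Sequence[ProfileHMM],
                 min_score: float = 8.0) -> list[DomainHit]:
    """Call non-overlapping class-labelled domains on one protein.

    Candidates from every model are pooled and accepted greedily by
    descending bit score; a candidate overlapping an accepted hit by more
    than 10% of the shorter hit's length is discarded.  Accepted hits are
    re-scored by all models on their window (+-5 residues) to set the class
    (argmax; ties broken by model-name order), runner-up and margin.
    """
    if not models:
        raise ValueError("empty model set")
    models = sorted(models, key=lambda m: m.name)
    codes = _encode(seq)
    candidates: list[tuple[float, str, int, int]] = []
    for m in models:
        for score, start, end in _local_hits_one_model(m, codes, min_score):
            candidates.append((score, m.name, start, end))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    accepted: list[tuple[float, str, int, int]] = []
    for score, mname, start, end in candidates:
        ok = True
        for _, _, astart, aend in accepted:
            ov = min(end, aend) - max(start, astart) + 1
            shorter = min(end - start + 1, aend - astart + 1)
            if ov > OVERLAP_TOLERANCE * shorter:
                ok = False
                break
        if ok:
            accepted.append((score, mname, start, end))

    hits: list[DomainHit] = []
    for _score, _mname, start, end in accepted:
        w0 = max(0, start - 1 - RESCORE_PAD)
        w1 = min(codes.shape[0], end + RESCORE_PAD)
        window = codes[w0:w1]
        best_name, best_sc = None, -np.inf
        second_name, second_sc = None, -np.inf
        for m in models:
            sc, _, _ = _score_matrix_pass(m, window, "local", summed=False)
            if sc > best_sc:
                second_name, second_sc = best_name, best_sc
                best_name, best_sc = m.name, sc
            elif sc > second_sc:
                second_name, second_sc = m.name, sc
        margin = float(best_sc - second_sc) if second_name is not None else 0.0
        hit = DomainHit(seq_id=seq.id, class_name=best_name, start=start, end=end,
                        score=float(best_sc), runner_up_class=second_name,
                        margin=max(0.0, margin))
        best_model = next(m for m in models if m.name == best_name)
        hit.core_motif, hit.cys_flag = core_motif_report(hit, best_model, seq)
        hits.append(hit)
    hits.sort(key=lambda h: h.start)
    return hits


def core_motif_report(hit: DomainHit, hmm: ProfileHMM, seq: SequenceRecord,
                      core_columns: tuple[int, int] | None = None,
                      variable_core: int | None = None) -> tuple[str, bool]:
    """Residues aligned to the model's core (KxGS) columns, plus the Cys flag.

    Core columns whose match state is deleted in the Viterbi path are filled
    with ``-`` and force the flag to False.
    """
    lo, hi, var = _model_core_columns(hmm)
    if core_columns is not None:
        lo, hi = core_columns
    if variable_core is not None:
        var = variable_core
    w0 = max(0, hit.start - 1 - RESCORE_PAD)
    w1 = min(len(seq.residues), hit.end + RESCORE_PAD)
    path = viterbi_align(hmm, seq.residues[w0:w1], mode="local")
    pos = path.match_positions()
    motif = []
    for col in range(lo, hi + 1):
        p = pos.get(col)
        motif.append(GAP if p is None else seq.residues[w0 + p - 1])
    vp = pos.get(var)
    cys = vp is not None and seq.residues[w0 + vp - 1] == "C"
    return "".join(motif), cys


def architecture(hits: Sequence[DomainHit]) -> Architecture:
    """Compact ordered hits into an architecture string with xN run-lengths."""
    hits = list(hits)
    if not hits:
        return Architecture(seq_id="", hits=[], string="", expansions=[])
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) != 1:
        raise ValueError(f"hits from multiple sequences: {sorted(seq_ids)}")
    hits.sort(key=lambda h: h.start)
    parts: list[str] = []
    expansions: list[tuple[str, int]] = []
    i = 0
    while i < len(hits):
        label = hits[i].display_class
        j = i
        while j + 1 < len(hits) and hits[j + 1].display_class == label:
            j += 1
        count = j - i + 1
        parts.append(label if count == 1 else f"{label}x{count}")
        if count >= 2:
            expansions.append((label, count))
        i = j + 1
    return Architecture(seq_id=hits[0].seq_id, hits=hits,
                        string="-".join(parts), expansions=expansions)


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def write_hits_tsv(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# seq_id\tclass\tstart\tend\tscore_bits\tmargin_bits"
                 "\tcore_motif\tcys_flag\n")
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.class_name}\t{h.start}\t{h.end}"
                     f"\t{h.score:.4f}\t{h.margin:.4f}\t{h.core_motif}"
                     f"\t{str(h.cys_flag).lower()}\n")


def write_hits_bed(hits: Sequence[DomainHit], path: str | Path) -> None:
    """BED6 export; 1-based inclusive coordinates become 0-based half-open."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start - 1}\t{h.end}\t{h.class_name}"
                     f"\t{h.score:.1f}\t+\n")


def write_architectures_tsv(archs: Sequence[Architecture], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# seq_id\tn_domains\tarchitecture\texpansions\n")
        for a in archs:
            exp = ",".join(f"{c}:{n}" for c, n in a.expansions)
            fh.write(f"{a.seq_id}\t{len(a.hits)}\t{a.string}\t{exp}\n")
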