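"""Specificity-determining positions by mutual-information permutation Z-score.

A specificity-determining position (SDP) is an alignment column that is
conserved within each paralog group but systematically different between
groups — the signature of functional divergence after gene duplication.  The
statistic is the mutual information (bits) between residue identity and group
label, estimated from pseudocount-smoothed counts over non-gap residues.  Its
null distribution comes from permuting the group labels across rows; one
label permutation per iteration is shared by all columns so that Z-scores are
comparable between columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AMINO_ACIDS, Alignment

Z_DEGENERATE_SD = 1e-12


@dataclass
class GroupedAlignment:
    """An alignment whose every row carries a group label; k >= 2 groups."""

    aln: Alignment

    def __post_init__(self) -> None:
        missing = [r.id for r in self.aln.records if r.id not in self.aln.groups]
        if missing:
            raise ValueError(f"rows without group labels: {missing[:5]}")
        labels = self.aln.group_labels()
        if len(labels) < 2:
            raise ValueError("need at least 2 groups for SDP analysis")
        sizes = {g: sum(1 for r in self.aln.records if self.aln.groups[r.id] == g)
                 for g in labels}
        small = [g for g, s in sizes.items() if s < 2]
        if small:
            raise ValueError(f"groups with fewer than 2 rows: {small}")
        self.labels = labels
        self.k = len(labels)

    def group_index(self) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.labels)}
        return np.array([lookup[self.aln.groups[r.id]] for r in self.aln.records])


@dataclass
class SDPResult:
    columns: np.ndarray          # 1-based column numbers
    mi: np.ndarray               # observed MI, bits
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    rank: np.ndarray             # permutation of 1..L, rank 1 = highest Z
    coverage_ok: np.ndarray      # bool, per-group coverage above threshold
    group_n: np.ndarray          # (k, L) non-gap counts per group
    labels: list[str] = field(default_factory=list)
    selected: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.columns.shape[0]

    def to_tsv(self, path: str | Path, consensus: dict[str, str] | None = None
               ) -> None:
        """Write the SDP table; ``consensus`` maps group -> consensus string."""
        with open(path, "w") as fh:
            fh.write("# column\tmi_bits\tnull_mean\tnull_sd\tz\trank\tselected"
                     "\tcoverage_ok\tgroup_consensus\n")
            for i in range(self.L):
                sel = bool(self.selected[i]) if self.selected is not None else False
                cons = ""
                if consensus:
                    cons = ",".join(f"{g}:{consensus[g][i]}" for g in self.labels)
                fh.write(f"{self.columns[i]}\t{self.mi[i]:.6f}"
                         f"\t{self.null_mean[i]:.6f}\t{self.null_sd[i]:.6f}"
                         f"\t{self.z[i]:.4f}\t{self.rank[i]}"
                         f"\t{str(sel).lower()}\t{str(bool(self.coverage_ok[i])).lower()}"
                         f"\t{cons}\n")


@dataclass
class SpecificityLogo:
    """Per-group residue frequency stacks for one selected column.

    Frequencies are relative to group size including gaps, so each group's
    stack sums to at most 1.
    """

    column: int
    stacks: dict[str, np.ndarray]     # group -> (20,) frequencies


def _mi_all_columns(codes: np.ndarray, gidx: np.ndarray, k: int,
                    alpha: float) -> np.ndarray:
    """Mutual information (bits) of every column between residue and group.

    ``codes`` is the integer residue matrix (n, L); gaps (-1) and unknowns
    (20) are excluded from the counts.  ``alpha`` is added to every
    (observed residue, group) cell of a column before normalising.
    """
    n, L = codes.shape
    valid = (codes >= 0) & (codes < 20)
    col_idx = np.broadcast_to(np.arange(L), (n, L))
    flat = (gidx[:, None] * 20 + np.where(valid, codes, 0)) * L + col_idx
    counts = np.bincount(flat[valid].ravel(), minlength=k * 20 * L
                         ).reshape(k, 20, L).astype(float)
    observed = counts.sum(axis=0) > 0                  # (20, L)
    counts = counts + alpha * observed[None, :, :]
    tot = counts.sum(axis=(0, 1))                      # (L,)
    safe_tot = np.where(tot > 0, tot, 1.0)
    joint = counts / safe_tot
    pg = joint.sum(axis=1)                             # (k, L)
    pa = joint.sum(axis=0)                             # (20, L)
    denom = pg[:, None, :] * pa[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / denom)
    term = np.where((joint > 0) & (denom > 0), term, 0.0)
    mi = term.sum(axis=(0, 1))
    return np.where(tot > 0, np.maximum(mi, 0.0), 0.0)


def column_mi(ga: GroupedAlignment, col: int, alpha: float = 0.5) -> float:
    """MI between residue and group for one 1-based column, in bits."""
    ga.aln._check_col(col)
    codes = ga.aln.codes()[:, [col - 1]]
    return float(_mi_all_columns(codes, ga.group_index(), ga.k, alpha)[0])


def sdp_zscores(ga: GroupedAlignment, n_perm: int = 1000, seed: int = 0,
                alpha: float = 0.5, min_coverage: float = 0.5) -> SDPResult:
    """Permutation Z-score of the residue/group MI for every column.

    Group labels are permuted across rows ``n_perm`` times (seeded); the same
    permutation is applied to every column within an iteration.  Columns with
    a degenerate null (sd < 1e-12) get Z = 0.  Ranks are by descending Z with
    ties broken by column order.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    codes = ga.aln.codes()
    gidx = ga.group_index()
    k = ga.k
    n, L = codes.shape

    mi_obs = _mi_all_columns(codes, gidx, k, alpha)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, L))
    for p in range(n_perm):
        null[p] = _mi_all_columns(codes, rng.permutation(gidx), k, alpha)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.where(sd < Z_DEGENERATE_SD, 0.0, (mi_obs - mean) / np.where(sd > 0, sd, 1.0))

    order = np.argsort(-z, kind="stable")
    rank = np.empty(L, dtype=int)
    rank[order] = np.arange(1, L + 1)

    valid = (codes >= 0) & (codes < 20)
    group_n = np.zeros((k, L))
    group_size = np.zeros(k)
    for g in range(k):
        rows = gidx == g
        group_size[g] = rows.sum()
        group_n[g] = valid[rows].sum(axis=0)
    coverage_ok = np.all(group_n >= min_coverage * group_size[:, None], axis=0)

    return SDPResult(columns=np.arange(1, L + 1), mi=mi_obs, null_mean=mean,
                     null_sd=sd, z=z, rank=rank, coverage_ok=coverage_ok,
                     group_n=group_n, labels=list(ga.labels))


def select_sdps(res: SDPResult, ga: GroupedAlignment, method: str = "top_k",
                param: float = 5, respect_coverage: bool = True
                ) -> tuple[list[int], list[SpecificityLogo]]:
    """Select SDP columns by ``top_k`` (k highest Z) or ``z_min`` (Z >= param).

    Columns failing the per-group coverage filter are not selectable unless
    ``respect_coverage`` is False.  Returns the selected 1-based columns (by
    descending Z) and a per-site group-frequency logo for each.
    """
    eligible = res.coverage_ok if respect_coverage else np.ones(res.L, bool)
    order = [int(c) for c in res.columns[np.argsort(-res.z, kind="stable")]
             if eligible[int(c) - 1]]
    if method == "top_k":
        kk = int(param)
        if kk > res.L:
            raise ValueError(f"top_k={kk} exceeds alignment length {res.L}")
        chosen = order[:kk]
    elif method == "z_min":
        chosen = [c for c in order if res.z[c - 1] >= param]
    else:
        raise ValueError(f"unknown selection method {method!r}")
    res.selected = np.isin(res.columns, chosen)

    codes = ga.aln.codes()
    gidx = ga.group_index()
    logos = []
    for col in chosen:
        stacks = {}
        for g, label in enumerate(ga.labels):
            rows = codes[gidx == g, col - 1]
            freq = np.zeros(20)
            for c in rows:
                if 0 <= c < 20:
                    freq[c] += 1.0
            stacks[label] = freq / rows.shape[0]
        logos.append(SpecificityLogo(column=col, stacks=stacks))
    return chosen, logos


def group_consensus(ga: GroupedAlignment) -> dict[str, str]:
    """Majority-rule consensus per group ('-' where gaps are the majority)."""
    codes = ga.aln.codes()
    gidx = ga.group_index()
    out = {}
    for g, label in enumerate(ga.labels):
        sub = codes[gidx == g]
        chars = []
        for j in range(sub.shape[1]):
            col = sub[:, j]
            gaps = (col < 0).sum()
            if gaps * 2 >= col.shape[0]:
                chars.append("-")
                continue
            counts = np.bincount(col[(col >= 0) & (col < 20)], minlength=20)
            if counts.sum() == 0:
                chars.append("X")
            else:
                chars.append(AMINO_ACIDS[int(np.argmax(counts))])
        out[label] = "".join(chars)
    return out
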