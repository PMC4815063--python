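"""Ground-truth simulator for MAP-like microtubule-associated protein families.

The generator emulates the evolutionary structure of the MAPT/MAP2/MAP4
family: a single ancestral gene, two duplications predating the species
radiation (MAP4 -> ancestor -> MAP2 + MAPT), three or four homologous
~33-column microtubule-binding domains (MTBDs) near the C-terminus with a
conserved KxGS core, class-specific planted residues at designated repeat
columns (the specificity-determining positions, e.g. Ile/Val in repeats 1
and 4 vs Cys in 2 and 3), a systematic deletion column (position 12) in
repeats 1-3, a fast-evolving low-conservation N-terminal projection region,
and an optional icefish-like tandem expansion of one repeat (4x copies of
repeat 2 with Lys->Arg adjacent to the core Cys).

Substitutions follow a 20-letter Jukes-Cantor-style uniform-replacement
process: on a branch of length ``b`` substitutions/site a site changes with
probability ``(19/20) * (1 - exp(-20 b / 19))``, to a uniformly drawn
different residue.  Per-column rate multipliers impose the family's
conservation structure (slow planted/core columns, fast N-terminus).
Indels are modelled as N-terminal deletions only; MTBD cores evolve gap-free
apart from the fixed deletion column.  All randomness flows from a single
seed, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .seqio import (AA_INDEX, AMINO_ACIDS, Alignment, SequenceRecord,
                    write_fasta, write_alignment)

#: 33-column MTBD consensus; columns 15-18 hold the KxGS core (x = column 16)
REPEAT_CONSENSUS = "LQTAPVPMPDLKNV" + "KCGS" + "KDNIKHVPGGGSVQI"
CORE_COLUMNS = (15, 18)
VARIABLE_CORE_COLUMN = 16
KXGS_FIXED_COLUMNS = (15, 17, 18)

#: default planted specificity-determining positions, keyed by repeat column;
#: values map repeat index -> residue.  Column 16 is the I/V <-> C core swap
#: separating repeats 1+4 from 2+3.
DEFAULT_PLANTED_SDPS: dict[int, dict[int, str]] = {
    8:  {1: "P", 2: "T", 3: "T", 4: "P"},
    10: {1: "K", 2: "N", 3: "N", 4: "K"},
    11: {1: "G", 2: "A", 3: "S", 4: "E"},
    16: {1: "I", 2: "C", 3: "C", 4: "V"},
    20: {1: "V", 2: "I", 3: "I", 4: "D"},
}


class ConfigError(ValueError):
    pass


@dataclass
class Duplication:
    """A gene duplication on a species-tree branch ("root" = the stem above
    the species root, i.e. before the radiation)."""
    branch: str
    parent: str
    name: str
    stem: float = 0.1


@dataclass
class Expansion:
    """Tandem duplication of one repeat on one leaf lineage, with an adjacent
    replacement (icefish-like: 4x repeat 2, Lys->Arg before the core Cys)."""
    lineage: str
    paralog: str = "MAPT"
    repeat: int = 2
    copies: int = 4
    replacement_col: int = 15
    replacement: tuple[str, str] = ("K", "R")


@dataclass
class SimConfig:
    species_tree: str
    duplications: list[Duplication] = field(default_factory=lambda: [
        Duplication("root", "MAP4", "MAP2", stem=0.15),
        Duplication("root", "MAP2", "MAPT", stem=0.10),
    ])
    root_paralog: str = "MAP4"
    n_repeats: dict[str, int] | int = 4
    repeat_length: int = 33
    repeat_consensus: str = REPEAT_CONSENSUS
    deletion_column: int = 12
    deletion_repeats: tuple[int, ...] = (1, 2, 3)
    planted_sdps: dict[int, dict[int, str]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_PLANTED_SDPS.items()})
    nterm_length: int = 90
    nterm_rate_multiplier: float = 6.0
    sdp_rate_multiplier: float = 0.05
    core_rate_multiplier: float = 0.1
    repeat_rate_multiplier: float = 0.15
    expansion: Expansion | None = None
    indel_rate: float = 0.02
    #: shared divergence of every paralog between the (pre-radiation)
    #: duplications and the species root; keeps paralog clades resolvable
    radiation_stem: float = 0.05
    seed: int = 0

    # ------------------------------------------------------------------
    def paralogs(self) -> list[str]:
        out = [self.root_paralog]
        for d in self.duplications:
            out.append(d.name)
        return out

    def repeats_of(self, paralog: str) -> int:
        if isinstance(self.n_repeats, int):
            return self.n_repeats
        return self.n_repeats[paralog]

    def validate(self) -> None:
        errs = []
        try:
            tree = dendropy.Tree.get(data=self.species_tree, schema="newick")
        except Exception as exc:        # noqa: BLE001 - report as config error
            errs.append(f"species_tree does not parse: {exc}")
            tree = None
        if len(self.repeat_consensus) != self.repeat_length:
            errs.append("repeat_consensus length != repeat_length")
        for rate, what in ((self.nterm_rate_multiplier, "nterm_rate_multiplier"),
                           (self.sdp_rate_multiplier, "sdp_rate_multiplier"),
                           (self.core_rate_multiplier, "core_rate_multiplier"),
                           (self.repeat_rate_multiplier, "repeat_rate_multiplier"),
                           (self.indel_rate, "indel_rate"),
                           (self.radiation_stem, "radiation_stem")):
            if rate < 0:
                errs.append(f"{what} must be >= 0")
        if self.nterm_rate_multiplier < 1:
            errs.append("nterm_rate_multiplier must be >= 1")
        for col, mapping in self.planted_sdps.items():
            if not 1 <= col <= self.repeat_length:
                errs.append(f"planted SDP column {col} outside repeat length")
            for r, aa in mapping.items():
                if aa not in AMINO_ACIDS:
                    errs.append(f"planted residue {aa!r} at column {col} invalid")
        paralogs = [self.root_paralog]
        if tree is not None:
            labels = {"root"}
            labels.update(l.taxon.label for l in tree.leaf_node_iter())
            labels.update(nd.label for nd in tree.preorder_internal_node_iter()
                          if nd.label)
            for d in self.duplications:
                if d.branch not in labels:
                    errs.append(f"duplication branch {d.branch!r} not in tree")
                if d.parent not in paralogs:
                    errs.append(f"duplication parent {d.parent!r} unknown")
                if d.stem < 0:
                    errs.append("duplication stem must be >= 0")
                paralogs.append(d.name)
        for p in set(paralogs):
            n = self.repeats_of(p) if not isinstance(self.n_repeats, int) \
                else self.n_repeats
            if n not in (3, 4):
                errs.append(f"n_repeats for {p} must be 3 or 4")
        if self.expansion is not None:
            e = self.expansion
            if tree is not None and e.lineage not in {
                    l.taxon.label for l in tree.leaf_node_iter()}:
                errs.append(f"expansion lineage {e.lineage!r} not a leaf")
            if e.paralog not in paralogs:
                errs.append(f"expansion paralog {e.paralog!r} unknown")
            if e.copies < 2:
                errs.append("expansion copies must be >= 2")
            if not 1 <= e.repeat <= 4:
                errs.append("expansion repeat index out of range")
            if not 1 <= e.replacement_col <= self.repeat_length:
                errs.append("expansion replacement column outside repeat")
        if errs:
            raise ConfigError("; ".join(errs))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedFamily:
    records: list[SequenceRecord]           # unaligned proteins, species|paralog
    alignment: Alignment                    # family alignment, groups = paralog
    column_blocks: list[tuple[str, int, int]]   # (label, start, end), 1-based
    repeat_alignment: Alignment             # one 33-col row per repeat instance
    truth_architectures: dict[str, str]
    truth_sdp_columns: dict[int, dict[int, str]]  # repeat col -> repeat -> residue
    tree: str                               # species tree, newick
    config: SimConfig


# ---------------------------------------------------------------------------
# evolution primitives
# ---------------------------------------------------------------------------

def _substitution_prob(branch_length: float | np.ndarray) -> np.ndarray:
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * np.asarray(branch_length)))


def _evolve(codes: np.ndarray, brlen: float, col_mult: np.ndarray,
            nterm_mask: np.ndarray, indel_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    alive = out >= 0
    p = _substitution_prob(brlen * col_mult)
    hit = alive & (rng.random(out.shape[0]) < p)
    if hit.any():
        out[hit] = (out[hit] + 1 + rng.integers(0, 19, size=int(hit.sum()))) % 20
    if indel_rate > 0 and brlen > 0:
        dele = alive & nterm_mask & (rng.random(out.shape[0]) < indel_rate * brlen)
        out[dele] = -1
    return out


def _encode_str(s: str) -> np.ndarray:
    return np.array([AA_INDEX[c] if c != "-" else -1 for c in s], dtype=np.int64)


def _decode(codes: np.ndarray, keep_gaps: bool) -> str:
    chars = []
    for c in codes:
        if c < 0:
            if keep_gaps:
                chars.append("-")
        else:
            chars.append(AMINO_ACIDS[c])
    return "".join(chars)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate_family(cfg: SimConfig) -> SimulatedFamily:
    """Evolve the configured family and return sequences plus ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.repeat_length
    C = cfg.nterm_length + 4 * R      # gene layout: nterm + up to 4 repeat blocks

    # per-column rate multipliers and masks (shared by all paralogs)
    col_mult = np.ones(C)
    nterm_mask = np.zeros(C, dtype=bool)
    nterm_mask[:cfg.nterm_length] = True
    col_mult[:cfg.nterm_length] = cfg.nterm_rate_multiplier
    for r in range(1, 5):
        base = cfg.nterm_length + (r - 1) * R
        col_mult[base:base + R] = cfg.repeat_rate_multiplier
        for col in cfg.planted_sdps:
            col_mult[base + col - 1] = cfg.sdp_rate_multiplier
        for col in KXGS_FIXED_COLUMNS:
            col_mult[base + col - 1] = cfg.core_rate_multiplier

    # ancestral gene
    consensus = _encode_str(cfg.repeat_consensus)
    anc = np.empty(C, dtype=np.int64)
    anc[:cfg.nterm_length] = rng.integers(0, 20, size=cfg.nterm_length)
    for r in range(1, 5):
        base = cfg.nterm_length + (r - 1) * R
        block = consensus.copy()
        for col, mapping in cfg.planted_sdps.items():
            if r in mapping:
                block[col - 1] = AA_INDEX[mapping[r]]
        if r in cfg.deletion_repeats:
            block[cfg.deletion_column - 1] = -1
        anc[base:base + R] = block

    def drop_unused_repeats(seq: np.ndarray, paralog: str) -> np.ndarray:
        n = cfg.repeats_of(paralog)
        out = seq.copy()
        for r in range(n + 1, 5):
            base = cfg.nterm_length + (r - 1) * R
            out[base:base + R] = -1
        return out

    tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick")

    def events_on(branch_label: str) -> list[Duplication]:
        return [d for d in cfg.duplications if d.branch == branch_label]

    genomes: dict[str, np.ndarray] = {cfg.root_paralog: anc}
    for d in events_on("root"):
        genomes[d.name] = _evolve(genomes[d.parent], d.stem, col_mult,
                                  nterm_mask, cfg.indel_rate, rng)
    if cfg.radiation_stem > 0:
        genomes = {p: _evolve(seq, cfg.radiation_stem, col_mult, nterm_mask,
                              cfg.indel_rate, rng)
                   for p, seq in genomes.items()}

    leaf_genomes: dict[str, dict[str, np.ndarray]] = {}

    def recurse(node, genome: dict[str, np.ndarray]) -> None:
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            g2 = {p: _evolve(seq, b, col_mult, nterm_mask, cfg.indel_rate, rng)
                  for p, seq in genome.items()}
            label = child.taxon.label if child.is_leaf() else child.label
            if label:
                for d in events_on(label):
                    g2[d.name] = _evolve(g2[d.parent], d.stem, col_mult,
                                         nterm_mask, cfg.indel_rate, rng)
            if child.is_leaf():
                leaf_genomes[child.taxon.label] = g2
            else:
                recurse(child, g2)

    recurse(tree.seed_node, genomes)

    # ---- assemble sequences, truth and alignments --------------------------
    exp = cfg.expansion
    max_copies = {r: 1 for r in range(1, 5)}
    if exp is not None:
        max_copies[exp.repeat] = exp.copies

    blocks: list[tuple[str, int]] = [("nterm", cfg.nterm_length)]
    for r in range(1, 5):
        for _copy in range(max_copies[r]):
            blocks.append((f"R{r}", R))
    column_blocks = []
    pos = 1
    for label, width in blocks:
        column_blocks.append((label, pos, pos + width - 1))
        pos += width

    records: list[SequenceRecord] = []
    aln_rows: list[SequenceRecord] = []
    aln_groups: dict[str, str] = {}
    rep_rows: list[SequenceRecord] = []
    rep_groups: dict[str, str] = {}
    truth_arch: dict[str, str] = {}

    species_order = [l.taxon.label for l in tree.leaf_node_iter()]
    for species in species_order:
        for paralog in leaf_genomes[species]:    # insertion order: stable
            seq = drop_unused_repeats(leaf_genomes[species][paralog], paralog)
            sid = f"{species}|{paralog}"
            nrep = cfg.repeats_of(paralog)

            repeat_blocks: dict[int, list[np.ndarray]] = {}
            for r in range(1, nrep + 1):
                base = cfg.nterm_length + (r - 1) * R
                repeat_blocks[r] = [seq[base:base + R].copy()]
            expanded = (exp is not None and species == exp.lineage
                        and paralog == exp.paralog and exp.repeat <= nrep)
            if expanded:
                src = repeat_blocks[exp.repeat][0]
                copies = []
                for _ in range(exp.copies):
                    cp = src.copy()
                    old, new = exp.replacement
                    if cp[exp.replacement_col - 1] == AA_INDEX[old]:
                        cp[exp.replacement_col - 1] = AA_INDEX[new]
                    copies.append(cp)
                repeat_blocks[exp.repeat] = copies

            # alignment row over the global column layout
            row_parts = [seq[:cfg.nterm_length]]
            arch_labels: list[str] = []
            for r in range(1, 5):
                copies = repeat_blocks.get(r, [])
                for c in range(max_copies[r]):
                    if c < len(copies):
                        row_parts.append(copies[c])
                    else:
                        row_parts.append(np.full(R, -1, dtype=np.int64))
                arch_labels.extend([f"R{r}"] * len(copies))
            row = np.concatenate(row_parts)
            residues = _decode(row, keep_gaps=False)
            records.append(SequenceRecord(sid, residues))
            aln_rows.append(SequenceRecord(sid, _decode(row, keep_gaps=True)))
            aln_groups[sid] = paralog
            truth_arch[sid] = _compact(arch_labels)

            for r in range(1, nrep + 1):
                for c, block in enumerate(repeat_blocks[r], start=1):
                    rid = f"{sid}/R{r}.{c}"
                    rep_rows.append(SequenceRecord(rid, _decode(block, True)))
                    rep_groups[rid] = f"{paralog}_R{r}"

    fam_aln = Alignment(aln_rows, groups=aln_groups)
    rep_aln = Alignment(rep_rows, groups=rep_groups)
    return SimulatedFamily(
        records=records, alignment=fam_aln, column_blocks=column_blocks,
        repeat_alignment=rep_aln, truth_architectures=truth_arch,
        truth_sdp_columns={c: dict(m) for c, m in cfg.planted_sdps.items()},
        tree=cfg.species_tree, config=cfg)


def _compact(labels: list[str]) -> str:
    parts = []
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        n = j - i + 1
        parts.append(labels[i] if n == 1 else f"{labels[i]}x{n}")
        i = j + 1
    return "-".join(parts)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def random_ultrametric_tree(n_species: int, depth: float, rng: np.random.Generator,
                            names: list[str] | None = None) -> str:
    """Random bifurcating ultrametric species tree (newick, all tips at
    ``depth`` substitutions/site from the root)."""
    if names is None:
        names = [f"sp{i + 1:02d}" for i in range(n_species)]
    if len(names) != n_species:
        raise ValueError("names length mismatch")

    def build(tips: list[str], t0: float) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{depth - t0:.6f}"
        split_t = t0 + float(rng.uniform(0.2, 0.8)) * (depth - t0)
        cut = int(rng.integers(1, len(tips)))
        left = build(tips[:cut], split_t)
        right = build(tips[cut:], split_t)
        return f"({left},{right}):{split_t - t0:.6f}"

    if n_species == 1:
        return f"({names[0]}:{depth:.6f});"
    cut = int(rng.integers(1, n_species))
    left = build(list(names[:cut]), 0.0)
    right = build(list(names[cut:]), 0.0)
    return f"({left},{right});"


def map_family_default(n_species: int = 12, divergence: float = 0.2,
                       seed: int = 0, expansion: bool = True) -> SimConfig:
    """The default MAP-family study preset.

    Three paralogs (MAP4 -> MAP2 -> MAPT by two root duplications, stems
    0.15 and 0.10), four 33-column repeats each (12 repeat classes), five
    planted SDP columns, deletion column 12 in repeats 1-3, a 90-residue
    fast N-terminus, and an icefish-like 4x expansion of MAPT repeat 2 with
    K->R at column 15 on the lineage named "icefish".
    """
    rng = np.random.default_rng(seed)
    names = ["icefish"] + [f"sp{i + 1:02d}" for i in range(n_species - 1)]
    tree = random_ultrametric_tree(n_species, divergence, rng, names=names)
    exp = Expansion(lineage="icefish") if expansion else None
    return SimConfig(species_tree=tree, expansion=exp, seed=seed)


# ---------------------------------------------------------------------------
# truth tables on disk
# ---------------------------------------------------------------------------

def truth_tables(fam: SimulatedFamily, outdir: str | Path) -> dict[str, Path]:
    """Write sequences, truth alignments and truth tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fa",
        "alignment": outdir / "truth_alignment.sto",
        "repeats": outdir / "truth_repeats.sto",
        "architectures": outdir / "truth_arch.tsv",
        "sdp": outdir / "truth_sdp.tsv",
        "tree": outdir / "truth_tree.nwk",
    }
    write_fasta(fam.records, paths["sequences"])
    write_alignment(fam.alignment, paths["alignment"], "stockholm")
    write_alignment(fam.repeat_alignment, paths["repeats"], "stockholm")
    with open(paths["architectures"], "w") as fh:
        fh.write("# seq_id\tarchitecture\n")
        for sid in sorted(fam.truth_architectures):
            fh.write(f"{sid}\t{fam.truth_architectures[sid]}\n")
    with open(paths["sdp"], "w") as fh:
        fh.write("# repeat_column\tplanted\tresidues\n")
        for col in range(1, fam.config.repeat_length + 1):
            planted = col in fam.truth_sdp_columns
            res = ",".join(f"R{r}:{aa}" for r, aa in
                           sorted(fam.truth_sdp_columns.get(col, {}).items()))
            fh.write(f"{col}\t{str(planted).lower()}\t{res}\n")
    with open(paths["tree"], "w") as fh:
        fh.write(fam.tree.strip() + "\n")
    return paths


def load_truth(outdir: str | Path) -> dict:
    """Reload the truth tables written by :func:`truth_tables`."""
    outdir = Path(outdir)
    arch = {}
    with open(outdir / "truth_arch.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            sid, a = line.rstrip("\n").split("\t")
            arch[sid] = a
    sdp: dict[int, dict[int, str]] = {}
    with open(outdir / "truth_sdp.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            col, planted, res = line.rstrip("\n").split("\t")
            if planted == "true":
                sdp[int(col)] = {int(tok.split(":")[0][1:]): tok.split(":")[1]
                                 for tok in res.split(",") if tok}
    tree = (outdir / "truth_tree.nwk").read_text().strip()
    return {"architectures": arch, "sdp": sdp, "tree": tree}


# ---------------------------------------------------------------------------
# clade-profile generator for subHMM presence/absence studies
# ---------------------------------------------------------------------------

def simulate_clade_alignments(n_clades: int = 3, n_seqs: int = 24,
                              length: int = 120,
                              shared_motifs: tuple[tuple[int, int], ...] = (
                                  (10, 21), (40, 51), (80, 91)),
                              private_motifs: dict[int, tuple[tuple[int, int], ...]]
                              | None = None,
                              conservation: float = 0.85,
                              seed: int = 0) -> list[Alignment]:
    """Clade alignments with shared and clade-private conserved motif blocks.

    ``private_motifs`` maps a clade index to column ranges (1-based incl.)
    that are conserved only in that clade; everywhere else those columns are
    i.i.d. random, like the non-motif background.  Used to test that subHMM
    matching marks clade-private motifs absent in the other clades.
    """
    if private_motifs is None:
        private_motifs = {0: ((60, 71), (105, 116))}
    rng = np.random.default_rng(seed)
    shared_consensus = {c: int(rng.integers(0, 20))
                        for a, b in shared_motifs for c in range(a, b + 1)}
    out = []
    for clade in range(n_clades):
        cons = dict(shared_consensus)
        for a, b in private_motifs.get(clade, ()):
            for c in range(a, b + 1):
                cons[c] = int(rng.integers(0, 20))
        rows = []
        for s in range(n_seqs):
            codes = rng.integers(0, 20, size=length)
            for c, aa in cons.items():
                if rng.random() < conservation:
                    codes[c - 1] = aa
            rows.append(SequenceRecord(f"c{clade}s{s:03d}",
                                       "".join(AMINO_ACIDS[x] for x in codes)))
        out.append(Alignment(rows))
    return out
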