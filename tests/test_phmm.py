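import math

import numpy as np
import pytest

from taumap.phmm import (DD, DM, IM, II, MD, MI, MM, ModelBuildError,
                         ProfileHMM, build_phmm, forward_score,
                         information_content, logo_export, read_hmmer3,
                         read_model, sample_alignment, viterbi_align,
                         viterbi_score, write_model, LogoTable)
from taumap.seqio import AA_INDEX, AMINO_ACIDS, Alignment, SequenceRecord


def make_aln(rows, **kw):
    return Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)], **kw)


def delta_model(residues: str) -> ProfileHMM:
    """Deterministic model emitting exactly `residues` via match states."""
    L = len(residues)
    e = np.zeros((L, 20))
    for j, c in enumerate(residues):
        e[j, AA_INDEX[c]] = 1.0
    t = np.zeros((L + 1, 7))
    t[:, MM] = 1.0
    t[:, IM] = 1.0
    t[:, DM] = 1.0
    hmm = ProfileHMM("delta", e, np.full(20, 0.05), t, np.full(20, 0.05))
    hmm.validate()
    return hmm


def random_hmm(rng, L) -> ProfileHMM:
    e = rng.dirichlet(np.ones(20) * 0.5, size=L)
    t = np.zeros((L + 1, 7))
    for j in range(L + 1):
        if j < L:
            t[j, [MM, MI, MD]] = rng.dirichlet(np.ones(3))
        else:
            mmi = rng.dirichlet(np.ones(2))
            t[j, MM], t[j, MI] = mmi
        t[j, [IM, II]] = rng.dirichlet(np.ones(2))
        if 0 < j < L:
            t[j, [DM, DD]] = rng.dirichlet(np.ones(2))
        else:
            t[j, DM] = 1.0
    hmm = ProfileHMM("rand", e, np.full(20, 0.05), t, np.full(20, 0.05))
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# brute-force path enumerator (independent oracle)
# ---------------------------------------------------------------------------

def enumerate_paths(hmm: ProfileHMM, codes, mode: str):
    """Log2-odds of every legal path; local mode enumerates every contiguous
    window with entry/exit at match states."""
    with np.errstate(divide="ignore"):
        lt = np.log2(hmm.transitions)
        lm = np.log2(hmm.match_emissions) - np.log2(hmm.background)
        li = np.log2(hmm.insert_emissions) - np.log2(hmm.background)
    L = hmm.L
    out = []

    def extend(state, j, i, acc, window, glocal):
        n = len(window)
        if glocal:
            if j == L:
                if state == "M" and i == n:
                    out.append(acc + lt[L, MM])
                if state == "I" and i == n:
                    out.append(acc + lt[L, IM])
                if state == "D" and i == n:
                    out.append(acc + lt[L, DM])
        elif state == "M" and i == n:
            out.append(acc)          # free local exit after a match
        if state in ("M", "I") and i < n:
            tr = lt[j, MI] if state == "M" else lt[j, II]
            extend("I", j, i + 1, acc + tr + li[window[i]], window, glocal)
        if j < L:
            tr_m = {"M": lt[j, MM], "I": lt[j, IM], "D": lt[j, DM]}[state]
            if i < n:
                extend("M", j + 1, i + 1, acc + tr_m + lm[j, window[i]],
                       window, glocal)
            if state in ("M", "D"):
                tr_d = lt[j, MD] if state == "M" else lt[j, DD]
                extend("D", j + 1, i, acc + tr_d, window, glocal)

    if mode == "glocal":
        extend("M", 0, 0, 0.0, list(codes), True)
        return out
    n = len(codes)
    for a in range(n):
        for b in range(a + 1, n + 1):
            w = list(codes[a:b])
            for j0 in range(1, L + 1):
                extend("M", j0, 1, -math.log2(L) + lm[j0 - 1, w[0]], w, False)
    return out


def logsumexp2(v):
    v = np.asarray(v)
    m = v.max()
    return float(m + np.log2(np.exp2(v - m).sum()))


@pytest.mark.parametrize("mode", ["glocal", "local"])
def test_scores_match_brute_force_enumeration(mode):
    """Viterbi and forward equal exhaustive path enumeration on small models."""
    rng = np.random.default_rng(20240501)
    checked = 0
    for _ in range(60):
        L = int(rng.integers(1, 4))
        n = int(rng.integers(1, 5))
        hmm = random_hmm(rng, L)
        codes = rng.integers(0, 20, size=n)
        seq = "".join(AMINO_ACIDS[c] for c in codes)
        paths = enumerate_paths(hmm, codes, mode)
        if not paths:
            continue
        assert viterbi_score(hmm, seq, mode) == pytest.approx(max(paths), abs=1e-7)
        assert viterbi_align(hmm, seq, mode).score == pytest.approx(
            max(paths), abs=1e-7)
        assert forward_score(hmm, seq, mode) == pytest.approx(
            logsumexp2(paths), abs=1e-7)
        checked += 1
    assert checked >= 50


class TestBuild:
    def test_identical_rows_alpha_zero_gives_delta_emissions(self):
        h = build_phmm(make_aln(["ACD", "ACD"]), pseudocount_alpha=0.0,
                       weighting="none")
        assert h.L == 3
        assert h.match_emissions[0, AA_INDEX["A"]] == 1.0

    def test_gap_fraction_tie_becomes_insert_column(self):
        h = build_phmm(make_aln(["A-", "AA"]), match_gap_threshold=0.5)
        assert h.L == 1

    def test_pseudocount_formula_hand_example(self):
        # counts {A:2, C:1}, N=3, alpha=1, uniform bg
        h = build_phmm(make_aln(["A", "A", "C"]), pseudocount_alpha=1.0,
                       weighting="none")
        assert h.match_emissions[0, AA_INDEX["A"]] == pytest.approx(0.5125)
        assert h.match_emissions[0, AA_INDEX["C"]] == pytest.approx(0.2625)
        assert h.match_emissions[0, AA_INDEX["D"]] == pytest.approx(0.0125)
        assert h.match_emissions[0].sum() == pytest.approx(1.0)

    def test_all_gap_alignment_fails(self):
        with pytest.raises(ModelBuildError):
            build_phmm(make_aln(["A-", "-A"]), match_gap_threshold=0.4)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            build_phmm(make_aln(["AC", "AC"]), pseudocount_alpha=-1.0)

    def test_stochastic_vectors_sum_to_one(self, rng):
        chars = np.array(list(AMINO_ACIDS + "-"))
        rows = ["".join(rng.choice(chars, size=12)) for _ in range(8)]
        rows = ["A" * 12 if set(r) == {"-"} else r for r in rows]
        h = build_phmm(make_aln(rows))
        h.validate(tol=1e-9)

    def test_parameter_recovery_from_sampled_sequences(self, default_family):
        """Rebuilding from sequences emitted by a model recovers its match
        emissions within sampling error."""
        from taumap.seqio import subalignment_by_group
        src = build_phmm(subalignment_by_group(default_family.repeat_alignment,
                                               "MAPT_R4"), name="src")
        aln = sample_alignment(src, 3000, seed=99)
        rebuilt = build_phmm(aln, pseudocount_alpha=0.0, weighting="none",
                             match_gap_threshold=0.5)
        assert rebuilt.L == src.L
        err = np.abs(rebuilt.match_emissions - src.match_emissions).max()
        assert err < 0.03


class TestScoring:
    def test_single_state_delta_closed_form(self):
        h = delta_model("A")
        assert viterbi_score(h, "A", "local") == pytest.approx(math.log2(20))

    def test_forward_at_least_viterbi(self, rng):
        for _ in range(20):
            h = random_hmm(rng, int(rng.integers(2, 6)))
            seq = "".join(rng.choice(list(AMINO_ACIDS),
                                     size=int(rng.integers(2, 8))))
            for mode in ("local", "glocal"):
                assert forward_score(h, seq, mode) >= \
                    viterbi_score(h, seq, mode) - 1e-9

    def test_single_path_model_forward_equals_viterbi(self):
        h = delta_model("ACD")
        v = viterbi_score(h, "ACD", "glocal")
        f = forward_score(h, "ACD", "glocal")
        assert f == pytest.approx(v, abs=1e-9)

    def test_reversed_sequence_scores_differently(self, rng):
        h = random_hmm(rng, 4)
        seq = "ACDEFG"
        assert viterbi_score(h, seq, "glocal") != pytest.approx(
            viterbi_score(h, seq[::-1], "glocal"), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            viterbi_score(delta_model("A"), "")

    def test_viterbi_path_coordinates_are_consistent(self):
        h = delta_model("ACD")
        path = viterbi_align(h, "WACDW", "local")
        assert (path.seq_start, path.seq_end) == (2, 4)
        assert path.match_positions() == {1: 2, 2: 3, 3: 4}


class TestInformationContent:
    def test_delta_and_background_columns(self):
        h = delta_model("A")
        assert information_content(h)[0] == pytest.approx(math.log2(20))
        flat = ProfileHMM("bg", np.full((1, 20), 0.05), np.full(20, 0.05),
                          h.transitions.copy(), np.full(20, 0.05))
        assert information_content(flat)[0] == pytest.approx(0.0)

    def test_two_residue_column_hand_value(self):
        e = np.zeros((1, 20))
        e[0, 0] = e[0, 1] = 0.5
        h = ProfileHMM("h", e, np.full(20, 0.05),
                       delta_model("A").transitions.copy(), np.full(20, 0.05))
        assert information_content(h)[0] == pytest.approx(3.3219, abs=1e-4)

    def test_invariant_under_residue_permutation_with_uniform_bg(self, rng):
        e = rng.dirichlet(np.ones(20), size=3)
        t = delta_model("ACD").transitions.copy()
        h1 = ProfileHMM("a", e, np.full(20, 0.05), t, np.full(20, 0.05))
        perm = rng.permutation(20)
        h2 = ProfileHMM("b", e[:, perm], np.full(20, 0.05), t, np.full(20, 0.05))
        assert information_content(h1) == pytest.approx(information_content(h2))


class TestLogo:
    def test_letter_heights_sum_to_column_height(self, class_models, tmp_path):
        hmm = class_models[0]
        table = logo_export(hmm, tmp_path / "logo.tsv")
        for h, stack in zip(table.heights, table.letters):
            assert sum(v for _, v in stack) == pytest.approx(h, abs=1e-3)
        assert (tmp_path / "logo.tsv").exists()

    def test_delta_column_single_full_height_letter(self):
        table = LogoTable.from_hmm(delta_model("C"))
        assert len(table.letters[0]) == 1
        assert table.letters[0][0] == ("C", pytest.approx(math.log2(20)))

    def test_background_column_has_no_letters_above_threshold(self):
        h = delta_model("A")
        flat = ProfileHMM("bg", np.full((1, 20), 0.05), np.full(20, 0.05),
                          h.transitions.copy(), np.full(20, 0.05))
        table = LogoTable.from_hmm(flat)
        assert table.heights[0] == pytest.approx(0.0, abs=1e-9)
        assert table.letters[0] == []

    def test_svg_rendering_writes_file(self, tmp_path):
        from taumap.phmm import render_logo_svg
        render_logo_svg(LogoTable.from_hmm(delta_model("KCGS")),
                        tmp_path / "l.svg")
        assert (tmp_path / "l.svg").stat().st_size > 0


class TestSerialization:
    def test_roundtrip_is_bit_exact(self, class_models, tmp_path):
        hmm = class_models[0]
        p = tmp_path / "m.tsv"
        write_model(hmm, p)
        back = read_model(p)
        assert np.array_equal(back.match_emissions, hmm.match_emissions)
        assert np.array_equal(back.transitions, hmm.transitions)
        assert np.array_equal(back.background, hmm.background)
        assert back.name == hmm.name
        assert back.meta.get("core_columns") == hmm.meta["core_columns"]

    def test_hmmer3_ascii_import_matches_pyhmmer_model(self, tmp_path,
                                                       default_family):
        pyhmmer = pytest.importorskip("pyhmmer")
        from taumap.seqio import subalignment_by_group
        sub = subalignment_by_group(default_family.repeat_alignment, "MAPT_R4")
        alpha = pyhmmer.easel.Alphabet.amino()
        seqs = [pyhmmer.easel.TextSequence(name=r.id.encode(),
                                           sequence=r.residues.replace("-", "."))
                for r in sub.records[:10]]
        msa = pyhmmer.easel.TextMSA(name=b"m", sequences=seqs).digitize(alpha)
        builder = pyhmmer.plan7.Builder(alpha)
        hmm_py, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(alpha))
        p = tmp_path / "m.hmm"
        with open(p, "wb") as fh:
            hmm_py.write(fh)
        ours = read_hmmer3(p)
        assert ours.L == hmm_py.M
        # match emissions agree (HMMER alphabet order is alphabetical = ours)
        theirs = np.asarray(hmm_py.match_emissions)[1:, :]
        assert np.abs(ours.match_emissions - theirs).max() < 1e-4
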