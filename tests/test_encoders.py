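"""Hand-crafted encoders vs independent brute-force oracles."""

import numpy as np
import pytest

from rbpkit.encoders import (AA_INDEX, CONJOINT_CLASSES, CTD_GROUPS,
                             FeatureSet, PSSMProfile, blosum62_profile,
                             concat_features, conjoint_triad_counts,
                             encode_conjoint_triad, encode_ctd, encode_paac,
                             encode_pssm400, encode_recipe, read_pssm,
                             write_pssm, read_feature_table,
                             write_feature_table)
from rbpkit.seqio import STANDARD_AA
from rbpkit.synthetic_data import gen_pssm

from conftest import random_sequence


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)
# ---------------------------------------------------------------------------

def oracle_pssm400(matrix, sequence):
    out = np.zeros(400)
    for block, aa in enumerate(STANDARD_AA):
        for pos in range(len(sequence)):
            if sequence[pos] == aa:
                for col in range(20):
                    out[block * 20 + col] += matrix[pos][col]
    return out


def oracle_ctd(sequence):
    out = []
    L = len(sequence)
    for groups in CTD_GROUPS.values():
        cls = "".join(
            str(next(k for k, g in enumerate(groups) if c in g)) for c in sequence
        )
        for k in "012":
            out.append(cls.count(k) / L)
        for pair in ("01", "02", "12"):
            n = sum(
                1 for i in range(L - 1)
                if cls[i] + cls[i + 1] in (pair, pair[::-1])
            )
            out.append(n / (L - 1) if L > 1 else 0.0)
        for k in "012":
            hits = [i + 1 for i, c in enumerate(cls) if c == k]
            if not hits:
                out.extend([0.0] * 5)
                continue
            for frac in (0, 0.25, 0.5, 0.75, 1.0):
                j = max(1, int(np.floor(frac * len(hits) + 0.5)))
                out.append(100.0 * hits[j - 1] / L)
    return np.array(out)


def oracle_triad_counts(sequence):
    cls_of = {aa: k for k, g in enumerate(CONJOINT_CLASSES) for aa in g}
    counts = np.zeros(343)
    for i in range(len(sequence) - 2):
        a, b, c = (cls_of[x] for x in sequence[i : i + 3])
        counts[a * 49 + b * 7 + c] += 1
    return counts


def oracle_paac(sequence, lam, weight, props):
    L = len(sequence)
    freqs = np.array([sequence.count(aa) for aa in STANDARD_AA]) / L
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            a, b = AA_INDEX[sequence[i]], AA_INDEX[sequence[i + k]]
            total += np.mean([(props[j][a] - props[j][b]) ** 2 for j in range(3)])
        thetas.append(total / (L - k))
    thetas = np.array(thetas)
    denom = freqs.sum() + weight * thetas.sum()
    return np.concatenate([freqs, weight * thetas]) / denom


# ---------------------------------------------------------------------------
# PSSM-400
# ---------------------------------------------------------------------------

class TestPssm400:
    def test_single_residue(self, rng):
        row = rng.normal(size=20)
        fs = encode_pssm400(PSSMProfile("p", row[None, :], "synthetic"), "A")
        assert fs.width == 400
        np.testing.assert_allclose(fs.vector[:20], row)
        assert np.all(fs.vector[20:] == 0)

    def test_two_residue_sum(self, rng):
        m = rng.normal(size=(2, 20))
        fs = encode_pssm400(PSSMProfile("p", m, "synthetic"), "AA")
        np.testing.assert_allclose(fs.vector[:20], m.sum(axis=0))

    def test_matches_double_loop_oracle(self, rng):
        seq = random_sequence(rng, 12)
        m = rng.normal(size=(12, 20))
        fs = encode_pssm400(PSSMProfile("p", m, "synthetic"), seq)
        np.testing.assert_allclose(fs.vector, oracle_pssm400(m, seq), atol=1e-9)

    def test_length_mismatch_is_error(self, rng):
        with pytest.raises(ValueError, match="rows"):
            encode_pssm400(PSSMProfile("p", rng.normal(size=(3, 20)), "synthetic"), "AA")


class TestBlosumProfile:
    def test_single_residue_row(self):
        prof = blosum62_profile("A")
        assert prof.matrix.shape == (1, 20)
        assert prof.matrix[0, AA_INDEX["A"]] == 4  # published BLOSUM62 (A,A)
        assert prof.source == "blosum62_fallback"

    def test_identical_residues_identical_rows(self):
        prof = blosum62_profile("AA")
        np.testing.assert_array_equal(prof.matrix[0], prof.matrix[1])

    def test_composition_with_pssm400(self):
        prof = blosum62_profile("AC")
        fs = encode_pssm400(prof, "AC")
        np.testing.assert_allclose(fs.vector[:20], prof.matrix[0])
        c = AA_INDEX["C"]
        np.testing.assert_allclose(fs.vector[20 * c : 20 * c + 20], prof.matrix[1])


# ---------------------------------------------------------------------------
# C-T-D
# ---------------------------------------------------------------------------

class TestCtd:
    def test_width_147(self):
        assert encode_ctd("MKVAHLTQSTLDAK").width == 147

    def test_homopolymer(self):
        fs = encode_ctd("AAAAA")
        per = 21
        for p, groups in enumerate(CTD_GROUPS.values()):
            block = fs.vector[p * per : (p + 1) * per]
            cls_a = next(k for k, g in enumerate(groups) if "A" in g)
            expected_comp = np.eye(3)[cls_a]
            np.testing.assert_allclose(block[:3], expected_comp)
            np.testing.assert_allclose(block[3:6], 0.0)  # no transitions
            dist = block[6:].reshape(3, 5)
            np.testing.assert_allclose(dist[cls_a], [20, 20, 60, 80, 100])
            for k in range(3):
                if k != cls_a:
                    np.testing.assert_allclose(dist[k], 0.0)

    def test_normalization_properties(self, random_sequences):
        for seq in random_sequences[:10]:
            vec = encode_ctd(seq).vector.reshape(7, 21)
            np.testing.assert_allclose(vec[:, :3].sum(axis=1), 1.0)
            assert np.all(vec[:, 3:6].sum(axis=1) <= 1.0 + 1e-12)

    def test_matches_class_string_oracle(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 30)
            np.testing.assert_allclose(
                encode_ctd(seq).vector, oracle_ctd(seq), atol=1e-9
            )

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            encode_ctd("")


# ---------------------------------------------------------------------------
# Conjoint triad
# ---------------------------------------------------------------------------

class TestConjointTriad:
    def test_single_window(self):
        fs = encode_conjoint_triad("AAA")  # A is in class 0
        assert fs.width == 343
        assert fs.vector[0] == 1.0
        assert np.sum(fs.vector != 0) == 1

    def test_counts_sum_to_windows(self, random_sequences):
        for seq in random_sequences[:10]:
            if len(seq) >= 3:
                assert conjoint_triad_counts(seq).sum() == len(seq) - 2

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 25)
            np.testing.assert_allclose(
                conjoint_triad_counts(seq), oracle_triad_counts(seq), atol=1e-9
            )

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            encode_conjoint_triad("MK")


# ---------------------------------------------------------------------------
# PAAC
# ---------------------------------------------------------------------------

class TestPaac:
    def test_lam_zero_is_plain_composition(self):
        fs = encode_paac("MKVAHLTQ", lam=0)
        assert fs.width == 20
        np.testing.assert_allclose(fs.vector.sum(), 1.0)
        assert fs.vector[AA_INDEX["M"]] == pytest.approx(1 / 8)

    def test_homopolymer_correlations_vanish(self):
        # identical residues give zero squared property differences, so the
        # correlation tier contributes nothing and the vector is plain AAC
        fs = encode_paac("GGGGG", lam=2, weight=0.05)
        assert fs.width == 22
        np.testing.assert_allclose(fs.vector[20:], 0.0, atol=1e-15)
        assert fs.vector[AA_INDEX["G"]] == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self, rng):
        from rbpkit.encoders import _PAAC_PROPS

        for _ in range(10):
            seq = random_sequence(rng, 15)
            got = encode_paac(seq, lam=3, weight=0.05)
            np.testing.assert_allclose(
                got.vector, oracle_paac(seq, 3, 0.05, _PAAC_PROPS), atol=1e-9
            )

    def test_length_not_exceeding_lam_is_error(self):
        with pytest.raises(ValueError):
            encode_paac("MKV", lam=3)


# ---------------------------------------------------------------------------
# composition, permutation sensitivity, IO
# ---------------------------------------------------------------------------

class TestConcatAndRecipes:
    def test_composite_widths(self, rng):
        seq = random_sequence(rng, 40)
        pssm = gen_pssm(seq, seed=0)
        assert encode_recipe(seq, "pssm400+ctd+triad", pssm=pssm).width == 890
        assert encode_recipe(seq, "ctd+triad").width == 490
        assert encode_recipe(seq, "pssm400+ctd+paac", pssm=pssm).width == 597

    def test_single_part_identity(self):
        fs = encode_ctd("MKVAHLTQ", protein_id="p")
        assert concat_features([fs]) is fs

    def test_id_mismatch_is_error(self):
        a = encode_ctd("MKVAHLTQ", protein_id="p1")
        b = encode_ctd("MKVAHLTQ", protein_id="p2")
        with pytest.raises(ValueError, match="mismatch"):
            concat_features([a, b])

    def test_blosum_fallback_warns(self, caplog):
        with caplog.at_level("WARNING"):
            fs = encode_recipe("MKVAHLTQSTLDAK", "pssm400+ctd+triad", "p")
        assert fs.width == 890
        assert any("BLOSUM62" in m for m in caplog.messages)


class TestPermutationSensitivity:
    # two sequences with identical composition but different order must
    # encode differently for the order-aware encoders
    A, B = "HLTHAQSTLDAK", "KHLTHAQSTLDA"

    def test_conjoint_triad(self):
        assert not np.allclose(encode_conjoint_triad(self.A).vector,
                               encode_conjoint_triad(self.B).vector)

    def test_ctd(self):
        assert not np.allclose(encode_ctd(self.A).vector, encode_ctd(self.B).vector)

    def test_paac_lam1(self):
        assert not np.allclose(encode_paac(self.A, lam=1).vector,
                               encode_paac(self.B, lam=1).vector)

    def test_widths_constant_across_inputs(self, random_sequences):
        widths = {
            (encode_ctd(s).width, encode_conjoint_triad(s).width,
             encode_paac(s, lam=4).width)
            for s in random_sequences if len(s) > 4
        }
        assert widths == {(147, 343, 24)}


class TestPssmIO:
    def test_plain_roundtrip(self, tmp_path, rng):
        prof = gen_pssm(random_sequence(rng, 8), seed=1)
        path = tmp_path / "p.pssm"
        write_pssm(prof, path)
        again = read_pssm(path)
        np.testing.assert_allclose(again.matrix, prof.matrix)

    def test_psiblast_ascii_reordered(self, tmp_path):
        # PSI-BLAST column order differs from the package's alphabetical one
        order = "A R N D C Q E G H I L K M F P S T W Y V".split()
        lines = ["", "Last position-specific scoring matrix computed",
                 "            " + "   ".join(order + order)]
        values = list(range(20))
        lines.append("    1 M  " + " ".join(str(v) for v in values)
                     + " " + " ".join("0" for _ in range(20)) + "  0.0 0.0")
        path = tmp_path / "blast.pssm"
        path.write_text("\n".join(lines) + "\n")
        prof = read_pssm(path, "m")
        assert prof.matrix.shape == (1, 20)
        for file_col, aa in enumerate(order):
            assert prof.matrix[0, AA_INDEX[aa]] == values[file_col]

    def test_feature_table_roundtrip(self, tmp_path, rng):
        feats = [FeatureSet(f"p{i}", rng.normal(size=5), "test") for i in range(3)]
        path = tmp_path / "feats.tsv"
        write_feature_table(feats, path)
        again = read_feature_table(path)
        assert [f.protein_id for f in again] == ["p0", "p1", "p2"]
        for a, b in zip(feats, again):
            np.testing.assert_allclose(a.vector, b.vector, atol=1e-9)
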