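"""Spectral IO, cosine scoring, similarity matrix and network tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytodiv.spectra import (
    CompoundSimilarityMatrix,
    FragmentationSpectrum,
    SimilarityParams,
    SpectralLibrary,
    build_network,
    build_similarity_matrix,
    cosine_similarity,
    read_mgf,
    write_mgf,
)

RAW1 = SimilarityParams(min_matched_peaks=1, intensity_transform="raw")


def spec(cid, mz, inten, precursor=500.0):
    return FragmentationSpectrum(compound_id=cid, precursor_mz=precursor,
                                 mz=np.asarray(mz, float),
                                 intensity=np.asarray(inten, float))


# ------------------------------------------------------------------- MGF IO

def test_single_block_parse(tmp_path):
    path = tmp_path / "one.mgf"
    path.write_text(
        "BEGIN IONS\nTITLE=cmpA\nPEPMASS=321.2\n"
        "100.1 5\n50.2 1\n200.0 3\nEND IONS\n")
    lib = read_mgf(path)
    assert len(lib) == 1
    sp = lib["cmpA"]
    assert sp.n_peaks == 3
    assert np.all(np.diff(sp.mz) > 0)  # emitted sorted ascending
    assert sp.mz[0] == pytest.approx(50.2)


def test_missing_pepmass_raises(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text("BEGIN IONS\nTITLE=cmpA\n100.0 1\nEND IONS\n")
    with pytest.raises(ValueError, match="PEPMASS"):
        read_mgf(path)


def test_missing_title_names_block(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text(
        "BEGIN IONS\nTITLE=ok\nPEPMASS=100\n10.0 1\nEND IONS\n"
        "BEGIN IONS\nPEPMASS=100\n10.0 1\nEND IONS\n")
    with pytest.raises(ValueError, match="block 1"):
        read_mgf(path)


def test_roundtrip_identity(tmp_path, small_library):
    path = tmp_path / "lib.mgf"
    write_mgf(small_library, path)
    back = read_mgf(path)
    assert back.compound_ids == small_library.compound_ids
    for cid in small_library.compound_ids:
        a, b = small_library[cid], back[cid]
        np.testing.assert_allclose(a.mz, b.mz, rtol=0, atol=1e-8)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=0, atol=1e-6)
        assert b.precursor_mz == pytest.approx(a.precursor_mz)


# ------------------------------------------------------------------- cosine

def test_self_similarity_is_one(small_library):
    for cid in small_library.compound_ids[:5]:
        s = small_library[cid]
        assert cosine_similarity(s, s, SimilarityParams(min_matched_peaks=1)) \
            == pytest.approx(1.0)


def test_hand_computed_half():
    """One matched unit peak of two: dot 1 over norms sqrt(2)*sqrt(2)."""
    a = spec("a", [100.00, 150.00], [1, 1])
    b = spec("b", [100.01, 200.00], [1, 1])
    assert cosine_similarity(a, b, RAW1) == pytest.approx(0.5)


def test_no_peaks_within_tolerance():
    a = spec("a", [100.0], [1])
    b = spec("b", [105.0], [1])
    assert cosine_similarity(a, b, RAW1) == 0.0


def test_min_matched_peaks_gate():
    a = spec("a", [100.0, 150.0], [1, 1])
    b = spec("b", [100.0, 150.0], [1, 1])
    assert cosine_similarity(a, b, SimilarityParams(min_matched_peaks=3)) == 0.0
    assert cosine_similarity(a, b, SimilarityParams(min_matched_peaks=2)) \
        == pytest.approx(1.0)


def test_greedy_matching_is_one_to_one():
    """Two a-peaks near one b-peak: only the closer pair is matched."""
    a = spec("a", [100.000, 100.015], [1, 1])
    b = spec("b", [100.005, 300.0], [1, 1])
    # best |dmz| pair is (100.000, 100.005); 100.015 is left unmatched
    assert cosine_similarity(a, b, RAW1) == pytest.approx(0.5)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50.0))
def test_symmetry_and_scale_invariance(seed, scale):
    rng = np.random.default_rng(seed)
    a = spec("a", np.sort(rng.uniform(50, 500, 6)), rng.uniform(0.1, 1, 6))
    b = spec("b", np.sort(rng.uniform(50, 500, 6)), rng.uniform(0.1, 1, 6))
    params = SimilarityParams(fragment_tol=5.0, min_matched_peaks=1)
    s_ab = cosine_similarity(a, b, params)
    s_ba = cosine_similarity(b, a, params)
    assert 0.0 <= s_ab <= 1.0
    assert s_ab == pytest.approx(s_ba, abs=1e-12)
    b_scaled = spec("b", b.mz, b.intensity * scale)
    assert cosine_similarity(a, b_scaled, params) == pytest.approx(s_ab, abs=1e-9)


# ------------------------------------------------------------------- matrix

def test_singleton_matrix():
    lib = SpectralLibrary({"only": spec("only", [100.0], [1])})
    eps = build_similarity_matrix(lib)
    np.testing.assert_array_equal(eps.epsilon, [[1.0]])


def test_matrix_matches_bruteforce_oracle(small_library):
    ids = small_library.compound_ids[:12]
    lib = SpectralLibrary({c: small_library[c] for c in ids})
    params = SimilarityParams(min_matched_peaks=1)
    eps = build_similarity_matrix(lib, params)
    for i, a in enumerate(eps.compound_ids):
        for j, b in enumerate(eps.compound_ids):
            expect = 1.0 if i == j else cosine_similarity(
                lib[a], lib[b], params)
            assert abs(eps.epsilon[i, j] - expect) <= 1e-12
    np.testing.assert_array_equal(eps.epsilon, eps.epsilon.T)


# ------------------------------------------------------------------ network

def _eps(ids, mat):
    return CompoundSimilarityMatrix(compound_ids=list(ids),
                                    epsilon=np.asarray(mat, float))


def test_below_threshold_gives_empty_network():
    eps = _eps("abc", [[1, .5, .6], [.5, 1, .4], [.6, .4, 1]])
    assert build_network(eps, min_cosine=0.7).edges == []


def test_triangle_survives_topk_default():
    eps = _eps("abc", [[1, .9, .9], [.9, 1, .9], [.9, .9, 1]])
    net = build_network(eps, min_cosine=0.7, topk=1000)
    assert len(net.edges) == 3


def test_topk_one_matches_rank_oracle():
    # path-shaped ranking: b is a's best, c's best is b, a is b's best
    ids = list("abcd")
    m = np.eye(4)
    pairs = {(0, 1): 0.95, (1, 2): 0.90, (2, 3): 0.85, (0, 2): 0.80,
             (1, 3): 0.75, (0, 3): 0.72}
    for (i, j), v in pairs.items():
        m[i, j] = m[j, i] = v
    eps = _eps(ids, m)
    net = build_network(eps, min_cosine=0.7, topk=1)
    # brute-force oracle: keep (i,j) iff j is i's single best and vice versa
    def best(i):
        scores = [(m[i, j], -j) for j in range(4) if j != i]
        return -max(scores)[1]
    expect = sorted((ids[i], ids[j]) for i in range(4) for j in range(i + 1, 4)
                    if m[i, j] >= 0.7 and best(i) == j and best(j) == i)
    assert sorted((u, v) for u, v, _ in net.edges) == expect


def test_topk_validation():
    eps = _eps("ab", [[1, .9], [.9, 1]])
    with pytest.raises(ValueError):
        build_network(eps, topk=0)
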