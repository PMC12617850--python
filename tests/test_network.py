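"""Modified-cosine similarity and molecular network construction."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sideroscan.network import build_network, export_graphml, modified_cosine
from sideroscan.spectra import FragmentSpectrum


def _spec(mz, inten, prec=500.0, sid="s", fid=None):
    return FragmentSpectrum(sid, prec, 1.0, np.asarray(mz, dtype=float),
                            np.asarray(inten, dtype=float), feature_id=fid or sid)


def _random_pair(rng, max_peaks=6, share=True):
    na, nb = rng.integers(2, max_peaks + 1), rng.integers(2, max_peaks + 1)
    mza = np.sort(rng.uniform(100, 500, na))
    mzb = np.sort(rng.uniform(100, 500, nb))
    if share:
        nshare = int(rng.integers(0, min(na, nb) + 1))
        mzb[:nshare] = np.sort(mza[:nshare] + rng.normal(0, 0.0008, nshare))
        mzb = np.sort(mzb)
    pa = rng.uniform(400, 900)
    pb = pa + rng.choice([0.0, 14.0157, rng.uniform(-50, 50)])
    a = _spec(mza, rng.uniform(1, 100, na), prec=pa, sid="a")
    b = _spec(mzb, rng.uniform(1, 100, nb), prec=pb, sid="b")
    return a, b


def optimal_assignment_score(a, b, tol_da=0.003, transform="sqrt"):
    """Independent oracle: optimal one-to-one pair assignment (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0
    wa = np.sqrt(a.intensity) if transform == "sqrt" else a.intensity
    wb = np.sqrt(b.intensity) if transform == "sqrt" else b.intensity
    shift = a.precursor_mz - b.precursor_mz
    weight = np.zeros((a.n_peaks, b.n_peaks))
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= tol_da or abs(d - shift) <= tol_da:
                weight[i, j] = wa[i] * wb[j]
    ri, cj = linear_sum_assignment(-weight)
    total = float(weight[ri, cj].sum())
    return total / float(np.linalg.norm(wa) * np.linalg.norm(wb))


class TestModifiedCosine:
    def test_self_similarity_exactly_one(self):
        s = _spec([100.0, 200.0, 300.0], [10.0, 50.0, 5.0])
        res = modified_cosine(s, s)
        assert res.score == 1.0
        assert res.n_matched == 3

    def test_disjoint_spectra_score_zero(self):
        a = _spec([100.0, 200.0], [10.0, 10.0], prec=500.0)
        b = _spec([150.0, 250.0], [10.0, 10.0], prec=500.0)
        res = modified_cosine(a, b)
        assert res.score == 0.0 and res.n_matched == 0

    def test_empty_spectrum_scores_zero(self):
        a = _spec([100.0], [10.0])
        e = FragmentSpectrum("e", 500.0, 1.0, np.array([]), np.array([]))
        assert modified_cosine(a, e).score == 0.0

    def test_precursor_shifted_analog_scores_one(self):
        # +CH2 homolog: all fragments and the precursor shifted together
        mz = np.array([86.06, 131.0815, 241.1183, 370.2, 440.25, 500.3])
        inten = np.array([100.0, 70.0, 20.0, 35.0, 25.0, 10.0])
        a = _spec(mz, inten, prec=751.4448, sid="a")
        b = _spec(mz + 14.01565, inten, prec=751.4448 + 14.01565, sid="b")
        res = modified_cosine(a, b)
        assert res.score == pytest.approx(1.0, abs=1e-12)
        assert res.n_matched == 6

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_pair(rng)
        r1 = modified_cosine(a, b)
        r2 = modified_cosine(b, a)
        assert r1.score == pytest.approx(r2.score, abs=1e-12)
        assert r1.n_matched == r2.n_matched

    def test_greedy_matches_optimal_on_small_spectra(self):
        """Greedy equals the optimal assignment in >=95% of 1,000 random
        <=6-peak pairs and never exceeds it."""
        rng = np.random.default_rng(42)
        equal = 0
        for _ in range(1000):
            a, b = _random_pair(rng)
            g = modified_cosine(a, b, tol_ppm=0.0, tol_da=0.003).score
            o = optimal_assignment_score(a, b)
            assert g <= o + 1e-9  # greedy never beats optimal
            if abs(g - o) <= 1e-9:
                equal += 1
        assert equal >= 950

    def test_agrees_with_matchms(self):
        """Independent cross-check against the matchms implementation."""
        from matchms import Spectrum
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(0)
        sim = ModifiedCosine(tolerance=0.003)
        for _ in range(100):
            a, b = _random_pair(rng)
            mine = modified_cosine(a, b, tol_ppm=0.0, tol_da=0.003, transform="raw")
            sa = Spectrum(mz=a.mz, intensities=a.intensity,
                          metadata={"precursor_mz": a.precursor_mz},
                          metadata_harmonization=False)
            sb = Spectrum(mz=b.mz, intensities=b.intensity,
                          metadata={"precursor_mz": b.precursor_mz},
                          metadata_harmonization=False)
            ref = sim.pair(sa, sb)
            assert mine.score == pytest.approx(float(ref["score"]), abs=1e-9)
            assert mine.n_matched == int(ref["matches"])


def _clique_spectra(n, n_peaks=6):
    mz = np.linspace(100, 600, n_peaks)
    inten = np.linspace(100, 40, n_peaks)
    return [_spec(mz, inten, prec=700.0, sid=f"n{i:02d}") for i in range(n)]


class TestBuildNetwork:
    def test_two_identical_spectra_single_edge(self):
        g = build_network(_clique_spectra(2))
        assert g.number_of_edges() == 1
        (_, _, d), = g.edges(data=True)
        assert d["score"] == pytest.approx(1.0)
        assert d["n_matched"] == 6

    def test_degree_cap_on_12_clique(self):
        g = build_network(_clique_spectra(12), max_neighbors=10)
        assert max(dict(g.degree).values()) <= 10

    def test_score_threshold_excludes_edge(self):
        a = _spec([100.0, 200.0, 300.0, 400.0, 450.0], [50.0] * 5, prec=500.0, sid="a")
        # share exactly 3 of 5 peaks -> cosine 0.6 < 0.7
        b = _spec([100.0, 200.0, 300.0, 410.0, 460.0], [50.0] * 5, prec=500.0, sid="b")
        res = modified_cosine(a, b)
        assert res.score < 0.7
        g = build_network([a, b], score_min=0.7, min_matched=3)
        assert g.number_of_edges() == 0

    def test_min_matched_excludes_edge(self):
        # identical 4-peak spectra: score 1.0 but only 4 matched ions
        mz = [100.0, 200.0, 300.0, 400.0]
        a = _spec(mz, [50.0] * 4, sid="a")
        b = _spec(mz, [50.0] * 4, sid="b")
        assert build_network([a, b], min_matched=5).number_of_edges() == 0
        assert build_network([a, b], min_matched=4).number_of_edges() == 1

    def test_fewer_than_two_spectra_empty_edge_set(self):
        g = build_network(_clique_spectra(1))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_family_members_form_one_component(self, default_scenario):
        from sideroscan.spectra import filter_peaks, remove_contaminant

        clean = [filter_peaks(remove_contaminant(s)) for s in default_scenario.spectra]
        g = build_network(clean)
        sid_nodes = {n for n in g.nodes if n.startswith("sid")}
        comps = [c for c in nx.connected_components(g) if c & sid_nodes]
        assert len(comps) == 1 and sid_nodes <= comps[0]

    def test_graphml_round_trip(self, tmp_path, default_scenario):
        from sideroscan.spectra import filter_peaks, remove_contaminant

        clean = [filter_peaks(remove_contaminant(s)) for s in default_scenario.spectra]
        g = build_network(clean)
        path = tmp_path / "net.graphml"
        export_graphml(g, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert {tuple(sorted(e)) for e in back.edges} == {
            tuple(sorted(e)) for e in g.edges
        }
        # node count equals the number of features with MS/MS
        assert back.number_of_nodes() == len(default_scenario.spectra)

    def test_empty_graph_exports(self, tmp_path):
        g = build_network([])
        export_graphml(g, tmp_path / "empty.graphml")
        assert nx.read_graphml(tmp_path / "empty.graphml").number_of_nodes() == 0
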