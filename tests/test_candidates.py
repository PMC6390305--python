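import numpy as np
import pandas as pd
import pytest

from triadscan.candidates import (
    TriadDesign,
    af_change,
    call_candidates,
    enrichment_tests,
    maf_matched_bootstrap,
)

from conftest import make_matrix


@pytest.fixture
def design():
    return TriadDesign(
        name="toy", te="TE", refs=("S", "N"),
        distances_km={("TE", "S"): 30.0, ("TE", "N"): 28.0, ("S", "N"): 58.0},
    )


def scan_frame(n, directional, p=None):
    """Minimal outlier-scan-shaped frame."""
    d = np.zeros(n, dtype=bool)
    d[directional] = True
    if p is None:
        p = np.full(n, 0.5)
    return pd.DataFrame({
        "scaffold": ["s0"] * n,
        "pos": np.arange(1, n + 1),
        "p": p,
        "call": np.where(d, "directional", "neutral"),
        "directional_envelope": d,
        "balancing_envelope": np.zeros(n, dtype=bool),
        "neutral_panel": ~d,
    })


class TestTriadDesign:
    def test_te_must_be_intermediate(self):
        with pytest.raises(ValueError, match="intermediate"):
            TriadDesign(name="bad", te="TE", refs=("S", "N"),
                        distances_km={("TE", "S"): 100.0, ("TE", "N"): 28.0,
                                      ("S", "N"): 58.0})

    def test_three_distinct_labels(self):
        with pytest.raises(ValueError, match="distinct"):
            TriadDesign(name="bad", te="TE", refs=("TE", "N"))

    def test_yaml_roundtrip(self, design, tmp_path):
        path = tmp_path / "triad.yaml"
        design.to_yaml(path)
        d2 = TriadDesign.from_yaml(path)
        assert d2.te == design.te and tuple(d2.refs) == tuple(design.refs)
        assert d2.distance("TE", "S") == 30.0


class TestCallCandidates:
    @pytest.mark.parametrize("flags,expected", [
        ((True, True, False), True),   # outlier in both TE comparisons only
        ((True, True, True), False),   # excluded by ref-vs-ref
        ((True, False, False), False),
        ((False, False, False), False),
    ])
    def test_conjunction_logic(self, design, flags, expected):
        r1 = scan_frame(3, [0] if flags[0] else [])
        r2 = scan_frame(3, [0] if flags[1] else [])
        r3 = scan_frame(3, [0] if flags[2] else [])
        out = call_candidates(r1, r2, r3, design)
        assert bool(out.loc[0, "candidate"]) is expected

    def test_mismatched_loci_raise(self, design):
        with pytest.raises(ValueError, match="different locus"):
            call_candidates(scan_frame(3, []), scan_frame(4, []),
                            scan_frame(3, []), design)

    def test_na_verdict_ineligible(self, design):
        r1 = scan_frame(2, [0])
        r2 = scan_frame(2, [0])
        r3 = scan_frame(2, [])
        r3.loc[0, "call"] = "NA"
        out = call_candidates(r1, r2, r3, design)
        assert not out.loc[0, "candidate"]

    def test_candidate_and_neutral_panel_disjoint(self, design):
        r1 = scan_frame(5, [0, 1])
        r2 = scan_frame(5, [0, 2])
        r3 = scan_frame(5, [])
        out = call_candidates(r1, r2, r3, design)
        assert not (out["candidate"] & out["neutral_panel"]).any()


class TestEnrichment:
    def make_candidates(self, n, idx):
        c = np.zeros(n, dtype=bool)
        c[idx] = True
        return pd.DataFrame({"candidate": c})

    def test_constructed_low_diversity_candidates(self, rng):
        n = 200
        theta_pi = np.sort(rng.random(n))
        d = rng.normal(size=n)
        cands = self.make_candidates(n, np.arange(20))  # lowest-diversity loci
        tab = enrichment_tests(cands, theta_pi, d)
        row = tab[tab["statistic"] == "theta_pi"].iloc[0]
        assert row["p"] < 0.05
        assert row["median_candidates"] < row["median_all"]

    def test_random_subset_calibrated(self, rng):
        n, reps = 150, 300
        theta_pi = rng.random(n)
        d = rng.normal(size=n)
        ps = []
        for _ in range(reps):
            cands = self.make_candidates(n, rng.choice(n, 15, replace=False))
            tab = enrichment_tests(cands, theta_pi, d)
            ps.append(tab.iloc[0]["p"])
        # roughly uniform: around half below 0.5, few below 0.05
        assert abs(np.mean(np.array(ps) < 0.5) - 0.5) < 0.12
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_too_few_candidates_raise(self, rng):
        cands = self.make_candidates(50, [1, 2])
        with pytest.raises(ValueError, match=">= 5"):
            enrichment_tests(cands, rng.random(50), rng.random(50))


class TestAfChange:
    def make_triad_matrix(self, freqs_by_pop, n=50, seed=0):
        rng = np.random.default_rng(seed)
        blocks, pops = [], []
        for pop, freqs in freqs_by_pop.items():
            blocks.append(np.column_stack(
                [rng.binomial(2, f, n) for f in freqs]).astype(np.int8))
            pops += [pop] * n
        return make_matrix(np.vstack(blocks), pops)

    def test_delta_p_arithmetic(self, design):
        # deterministic frequencies via hom/het construction
        n = 50
        te = np.column_stack([np.repeat([0, 1], [21, 29])]).astype(np.int8)
        s = np.column_stack([np.repeat([0, 1], [25, 25])]).astype(np.int8)
        nn = np.column_stack([np.repeat([0, 1], [25, 25])]).astype(np.int8)
        g = make_matrix(np.vstack([te, s, nn]), ["TE"] * n + ["S"] * n + ["N"] * n)
        cands = pd.DataFrame({"candidate": [False]})
        out = af_change(cands, g, design)
        assert out.loc[0, "abs_delta_p"] == pytest.approx(abs(29 / 100 - 25 / 100))

    def test_symmetric_refs_cancel(self, design):
        n = 50
        te = np.repeat([0, 1], [25, 25]).astype(np.int8)[:, None]
        s = np.repeat([0, 1], [30, 20]).astype(np.int8)[:, None]
        nn = np.repeat([0, 1], [20, 30]).astype(np.int8)[:, None]
        g = make_matrix(np.vstack([te, s, nn]), ["TE"] * n + ["S"] * n + ["N"] * n)
        out = af_change(pd.DataFrame({"candidate": [False]}), g, design)
        assert out.loc[0, "abs_delta_p"] == pytest.approx(0.0)

    def test_private_allele_flag(self, design):
        n = 20
        te = np.repeat([0, 1], [15, 5]).astype(np.int8)[:, None]
        zeros = np.zeros((n, 1), dtype=np.int8)
        g = make_matrix(np.vstack([te, zeros, zeros]),
                        ["TE"] * n + ["S"] * n + ["N"] * n)
        out = af_change(pd.DataFrame({"candidate": [False]}), g, design)
        assert bool(out.loc[0, "private"])


class TestMafMatchedBootstrap:
    def test_single_bin_target(self, rng):
        neutral = rng.uniform(0.0, 0.5, 500)
        target = rng.uniform(0.041, 0.059, 30)
        draws = maf_matched_bootstrap(neutral, target, n_boot=20, seed=1)
        for d in draws:
            assert len(d) == 30
            assert ((neutral[d] >= 0.04) & (neutral[d] < 0.06)).all()

    def test_mean_maf_matches(self, rng):
        neutral = rng.uniform(0.0, 0.5, 2000)
        target = rng.beta(2, 5, 100) * 0.5
        draws = maf_matched_bootstrap(neutral, target, n_boot=500, seed=2)
        means = [neutral[d].mean() for d in draws]
        assert abs(np.mean(means) - target.mean()) < 0.01

    def test_empty_bin_raises(self):
        neutral = np.full(100, 0.30)
        target = np.array([0.05])
        with pytest.raises(ValueError, match="empty"):
            maf_matched_bootstrap(neutral, target, n_boot=5, seed=3)
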