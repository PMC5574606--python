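"""Replicate-core aggregation, composition, megafauna screen, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isotroph.community import (
    CoreSample,
    compare_groups,
    composition,
    cores_to_frame,
    densities,
    exclude_megafauna,
    games_howell,
    pool_layer_means,
    sediment_descriptors,
    welch_anova,
)
from isotroph.simulate import load_fixture


def make_cores(n_cores=3, area=0.004, counts=None):
    counts = counts if counts is not None else {"worm": 5, "clam": 3}
    rows = []
    for c in range(n_cores):
        for layer in ("0-5 cm", "5-10 cm"):
            for taxon, k in counts.items():
                rows.append(
                    CoreSample(
                        core_id=f"c{c}",
                        site="NOW",
                        layer=layer,
                        taxon=taxon,
                        guild="FF/SDF" if taxon == "clam" else "SSDF",
                        count=k if layer == "0-5 cm" else max(0, k - 2),
                        c_biomass_mg=0.3 * k,
                        n_biomass_mg=0.05 * k,
                        area_m2=area,
                    )
                )
    return cores_to_frame(rows)


class TestDensities:
    def test_pooled_equals_sum_of_layer_means(self):
        s = densities(make_cores())
        t = s.table
        pooled = t.loc["0-10 cm (pooled)", "density_mean"]
        assert pooled == pytest.approx(
            t.loc["0-5 cm", "density_mean"] + t.loc["5-10 cm", "density_mean"],
            abs=1e-12,
        )

    def test_table2_layer_means_pool_to_printed_site_totals(self):
        t2 = load_fixture("table2")
        now = t2[t2.site == "NOW"]
        ls = t2[t2.site == "LS"]
        assert pool_layer_means(now.density_mean) == 10952
        assert pool_layer_means(now.c_biomass_mean) == 3190
        assert pool_layer_means(ls.c_biomass_mean) == 2110

    def test_doubling_area_halves_density(self):
        a = densities(make_cores(area=0.004)).table
        b = densities(make_cores(area=0.008)).table
        assert np.allclose(
            b.filter(like="mean").to_numpy(), a.filter(like="mean").to_numpy() / 2
        )

    def test_all_zero_counts(self):
        cores = make_cores(counts={"worm": 0})
        s = densities(cores)
        assert (s.table["density_mean"] == 0).all()
        assert (s.table["density_se"].fillna(0) == 0).all()

    def test_identical_replicates_have_zero_se(self):
        s = densities(make_cores(n_cores=4))
        assert s.table.loc["0-5 cm", "density_se"] == 0.0

    def test_se_scales_as_inverse_sqrt_n(self):
        base = make_cores(n_cores=1, counts={"worm": 5})
        varied = []
        for i, k in enumerate([3, 5, 9, 7]):
            c = make_cores(n_cores=1, counts={"worm": k})
            c["core_id"] = f"v{i}"
            varied.append(c)
        one = pd.concat(varied, ignore_index=True)
        reps = []
        for r in range(4):
            c = one.copy()
            c["core_id"] = c["core_id"] + f"_r{r}"
            reps.append(c)
        four = pd.concat(reps, ignore_index=True)
        se1 = densities(one).table.loc["0-5 cm", "density_se"]
        se4 = densities(four).table.loc["0-5 cm", "density_se"]
        # dispersion is unchanged under exact replication, so SE shrinks by
        # 1/sqrt(r) up to the ddof=1 small-sample factor sqrt(r(n-1)/(rn-1))
        n, r = 4, 4
        expected = se1 / np.sqrt(r) * np.sqrt(r * (n - 1) / (r * n - 1))
        assert se4 == pytest.approx(expected, rel=1e-9)

    def test_per_core_pooling_matches_when_layers_complete(self):
        cores = make_cores()
        a = densities(cores, pooling="layer-means").table
        b = densities(cores, pooling="per-core").table
        assert a.loc["0-10 cm (pooled)", "density_mean"] == pytest.approx(
            b.loc["0-10 cm (pooled)", "density_mean"]
        )

    def test_mixed_sites_rejected(self):
        cores = make_cores()
        cores.loc[0, "site"] = "LS"
        with pytest.raises(ValueError, match="single site"):
            densities(cores)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            densities(make_cores().iloc[0:0])


class TestMegafaunaExclusion:
    def test_ls_fixture_bivalves_excluded_with_printed_totals(self):
        cores = load_fixture("ls_megafauna_synthetic")
        kept, report = exclude_megafauna(cores, k=10.0)
        assert report["n_excluded"] == 3
        assert set(report["excluded"]["taxon"]) == {"Bathyarca glacialis"}
        assert report["c_biomass_per_m2"] == pytest.approx(3666, rel=1e-3)
        assert report["n_biomass_per_m2"] == pytest.approx(833, rel=1e-3)
        assert "Bathyarca glacialis" not in set(kept["taxon"])

    def test_homogeneous_community_untouched(self):
        cores = make_cores()
        kept, report = exclude_megafauna(cores)
        assert report["n_excluded"] == 0
        assert len(kept) == len(cores)

    def test_single_record_has_no_comparison_basis(self):
        cores = make_cores(n_cores=1, counts={"worm": 1}).iloc[:1]
        kept, report = exclude_megafauna(cores)
        assert report["n_excluded"] == 0
        assert len(kept) == 1


class TestComposition:
    def test_shares_sum_to_100(self):
        comp = composition(make_cores())
        for col in comp.columns:
            assert comp[col].sum() == pytest.approx(100.0, abs=0.5)

    def test_single_taxon_is_100(self):
        comp = composition(make_cores(counts={"worm": 4}))
        assert comp.loc["worm", "density_pct"] == pytest.approx(100.0)

    def test_scale_invariance(self):
        cores = make_cores()
        scaled = cores.copy()
        for col in ("count", "c_biomass_mg", "n_biomass_mg"):
            scaled[col] *= 7.0
        assert np.allclose(
            composition(cores).to_numpy(), composition(scaled).to_numpy()
        )

    def test_fragments_in_biomass_but_not_density(self):
        cores = make_cores()
        frag = cores.iloc[[0]].copy()
        frag["taxon"] = "fragments"
        frag["count"] = 0
        frag["c_biomass_mg"] = cores["c_biomass_mg"].sum()  # half of total C
        frag["fragment_flag"] = True
        comp = composition(pd.concat([cores, frag], ignore_index=True))
        assert comp.loc["fragments", "density_pct"] == 0.0
        assert comp.loc["fragments", "c_biomass_pct"] == pytest.approx(50.0)

    def test_guild_level_and_unknown_level(self):
        comp = composition(make_cores(), level="guild")
        assert set(comp.index) == {"FF/SDF", "SSDF"}
        with pytest.raises(ValueError, match="level"):
            composition(make_cores(), level="phylum")


class TestSedimentDescriptors:
    @pytest.mark.parametrize(
        "chl, phaeo, total, ratio",
        [(20.5, 60.5, 81.0, 0.34), (12.9, 64.5, 77.4, 0.2), (0.0, 10.0, 10.0, 0.0)],
    )
    def test_printed_table_values(self, chl, phaeo, total, ratio):
        out = sediment_descriptors(chl, phaeo)
        assert out["total_pigments"] == pytest.approx(total)
        assert out["chl_phaeo_ratio"] == ratio

    def test_zero_phaeo_is_missing(self):
        out = sediment_descriptors(5.0, 0.0)
        assert np.isnan(out["chl_phaeo_ratio"])
        assert out["total_pigments"] == 5.0


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        report = compare_groups(g, design="two-sample")
        assert report.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_group_falls_back_to_nonparametric(self):
        g = {"a": [2.0, 2.0, 2.0], "b": [1.0, 3.0, 5.0]}
        with pytest.warns(UserWarning, match="zero-variance"):
            report = compare_groups(g, design="two-sample")
        assert report.path == "mann-whitney"
        assert report.warnings

    def test_one_way_paths(self, rng):
        g = {k: rng.normal(0, 1, 12) for k in "abc"}
        parametric = compare_groups(g, design="one-way")
        assert parametric.path in ("anova", "welch-anova", "kruskal-wallis")
        forced = compare_groups(g, design="one-way", nonparametric=True)
        assert forced.path == "kruskal-wallis"

    def test_welch_anova_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        g = {k: rng.normal(i, 1 + i, 10) for i, k in enumerate("abc")}
        f, (df1, df2), p = welch_anova(list(g.values()))
        df = pd.DataFrame(
            [(k, v) for k, arr in g.items() for v in arr], columns=["g", "y"]
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)

    def test_two_way_interaction_table(self, rng):
        rows = []
        for site in ("NOW", "LS"):
            for guild in ("SDF", "SSDF", "P/S"):
                for _ in range(6):
                    rows.append(
                        {"value": rng.normal(0, 1), "site": site, "guild": guild}
                    )
        df = pd.DataFrame(rows)
        report = compare_groups(
            df, design="two-way", factors=("site", "guild"), value="value"
        )
        assert report.table is not None
        assert {"C(fa)", "C(fb)", "C(fa):C(fb)", "Residual"} <= set(report.table.index)

    def test_log10_transform_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            compare_groups(
                {"a": [1.0, -2.0, 1.5], "b": [1.0, 2.0, 2.5]},
                design="two-sample",
                log10_transform=True,
            )

    def test_posthoc_attached(self, rng):
        g = {k: rng.normal(0, 1, 10) for k in "abc"}
        report = compare_groups(g, design="one-way", posthoc=True)
        assert report.posthoc is not None and len(report.posthoc) == 3


class TestGamesHowell:
    def test_two_groups_equals_welch_t(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.4, 2.5, 14)
        gh = games_howell({"a": a, "b": b})
        welch_p = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert gh["pvalue"].iloc[0] == pytest.approx(welch_p, abs=1e-6)

    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        g = {k: rng.normal(i * 0.5, 1 + i, 8 + i) for i, k in enumerate("abc")}
        mine = games_howell(g).sort_values(["group_a", "group_b"])
        df = pd.DataFrame(
            [(k, v) for k, arr in g.items() for v in arr], columns=["g", "y"]
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g").sort_values(
            ["A", "B"]
        )
        assert np.allclose(mine["pvalue"].to_numpy(), ref["pval"].to_numpy(), atol=1e-8)
        assert np.allclose(mine["df"].to_numpy(), ref["df"].to_numpy(), rtol=1e-9)

    def test_requires_two_values_per_group(self):
        with pytest.raises(ValueError):
            games_howell({"a": [1.0], "b": [1.0, 2.0]})
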