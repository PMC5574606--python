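"""Synthetic-data generation and packaged study fixtures.

The generator emulates the statistical structure the analysis assumes:
consumer δ¹³C/δ¹⁵N signatures arise from mixtures of two TEF-shifted
end-member sources with Gaussian noise (the mixing model's generative form
run forward), and replicate-core count data are negative-binomially
overdispersed with lognormal per-individual biomass.  Every draw flows
from one explicitly seeded generator, so identical scenarios give
byte-identical tables.

:func:`load_fixture` returns the packaged transcriptions of the study's
printed tables (sediment descriptors, layer-resolved density/biomass,
relative composition) and of the δ values printed in the running text,
plus clearly-labelled synthetic companions (consumer table, end-member
table) for exercising the full pipeline.  Values whose provenance is
``synthetic`` or ``back-computed`` were invented or inverted from printed
rounded values and are stand-ins, not study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GUILDS, IsotopeRecord
from .mixing import SourceSpec, TEFSpec
from .trophic import BaselineSignature

__all__ = [
    "CommunityScenario",
    "generate_isotopes",
    "generate_cores",
    "load_fixture",
    "FIXTURES",
]

#: Fixture names resolvable by :func:`load_fixture`.
FIXTURES = (
    "table1",
    "table2",
    "table3",
    "text_values",
    "consumers_synthetic",
    "sources_synthetic",
    "baselines",
    "ls_megafauna_synthetic",
)

_DEFAULT_SOURCES = (
    SourceSpec("ice_algae", mean=(-16.1, 6.8), sd=(1.2, 0.8)),
    SourceSpec("pelagic_pom", mean=(-24.6, 5.6), sd=(1.3, 0.9)),
)


@dataclass
class CommunityScenario:
    """Parameters of one simulated benthic community.

    Defaults mirror the sampled study system: ~18 taxa per site, two
    end-member sources with POM-dominated diets, a 7.4‰ sediment δ¹⁵N
    baseline, 15 replicate half-cores of nominal area 0.003927 m²
    (half of a 10 cm diameter sub-core) sliced into 0-5 / 5-10 cm layers
    with ~95% of individuals in the surface layer, overdispersed counts
    and lognormal individual biomass around 0.25 mg C.
    """

    seed: int
    n_taxa: int = 18
    sources: tuple[SourceSpec, ...] = _DEFAULT_SOURCES
    tef: TEFSpec = TEFSpec()
    baseline: BaselineSignature = BaselineSignature(
        site="NOW", d15n_sediment=7.4, d13c_sediment=-20.6, sd=0.1, n=3
    )
    true_diets: np.ndarray | None = None
    true_tls: np.ndarray | None = None
    guild_assignment: tuple[str, ...] | None = None
    consumer_noise_sd: tuple[float, float] = (0.5, 0.5)
    samples_per_taxon: int = 1
    enrichment_per_level: float = 3.8
    n_cores: int = 15
    mean_count_per_core: float = 1.5
    overdispersion: float = 0.5
    layer_split: tuple[float, float] = (0.95, 0.05)
    biomass_log_mean: float = float(np.log(0.25))
    biomass_log_sigma: float = 1.0
    cn_ratio: float = 6.5
    area_m2: float = 0.003927
    megafauna: dict | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("scenario seed is mandatory")
        if any(s < 0 for s in self.consumer_noise_sd):
            raise ValueError("consumer noise sds must be >= 0")
        if self.true_diets is not None:
            p = np.atleast_2d(np.asarray(self.true_diets, dtype=float))
            if p.shape != (self.n_taxa, len(self.sources)):
                raise ValueError(
                    f"true_diets must have shape (n_taxa={self.n_taxa}, "
                    f"n_sources={len(self.sources)}), got {p.shape}"
                )
            if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("true_diets rows must lie on the simplex")
            self.true_diets = p


def _resolve_diets(scenario: CommunityScenario, rng: np.random.Generator) -> np.ndarray:
    if scenario.true_diets is not None:
        return scenario.true_diets
    k = len(scenario.sources)
    # POM-dominated by default: mean POM share ~0.7, matching the kind of
    # source partitioning the analysis is built to recover.
    pom = rng.beta(7.0, 3.0, size=scenario.n_taxa)
    if k == 2:
        return np.column_stack([1.0 - pom, pom])
    rest = rng.dirichlet(np.ones(k - 1), size=scenario.n_taxa)
    return np.column_stack([(1.0 - pom)[:, None] * rest[:, :-1], pom])


def generate_isotopes(
    scenario: CommunityScenario,
) -> tuple[list[IsotopeRecord], pd.DataFrame]:
    """Simulate consumer isotope records plus a truth table.

    Per taxon sample, each isotope is Σ_j p_j (S_j + C_j) + ε with S_j and
    C_j drawn per sample from the source and TEF distributions.  When
    ``true_tls`` is set, δ¹⁵N is instead pinned by inverting the
    trophic-level equation around the baseline, so zero-noise scenarios
    recover the pinned TLs exactly.  The truth table records each taxon's
    diet proportions and trophic level for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0]))
    diets = _resolve_diets(scenario, rng)
    mu = np.array([s.mean for s in scenario.sources])  # (k, D)
    omega = np.array([s.sd for s in scenario.sources])
    lam = np.asarray(scenario.tef.mean, dtype=float)
    tau = np.asarray(scenario.tef.sd, dtype=float)
    if mu.shape[1] != lam.shape[0] or mu.shape[1] != len(scenario.consumer_noise_sd):
        raise ValueError("isotope dimensionality of sources, TEF and noise must agree")
    noise = np.asarray(scenario.consumer_noise_sd, dtype=float)
    guilds = scenario.guild_assignment or tuple(
        GUILDS[i % (len(GUILDS) - 1)] for i in range(scenario.n_taxa)
    )
    if scenario.true_tls is not None:
        tls = np.asarray(scenario.true_tls, dtype=float)
        if tls.shape[0] != scenario.n_taxa:
            raise ValueError("true_tls must have one entry per taxon")

    records: list[IsotopeRecord] = []
    truth_rows = []
    for t in range(scenario.n_taxa):
        p = diets[t]
        mean_sig = p @ (mu + lam)
        for s in range(scenario.samples_per_taxon):
            src_draw = mu + rng.normal(0.0, 1.0, size=mu.shape) * omega
            tef_draw = lam + rng.normal(0.0, 1.0, size=lam.shape) * tau
            sig = p @ (src_draw + tef_draw) + rng.normal(0.0, 1.0, size=len(noise)) * noise
            if scenario.true_tls is not None:
                d15n_mean = (
                    scenario.baseline.d15n_sediment
                    + (tls[t] - 1.0) * scenario.enrichment_per_level
                )
                sig[1] = d15n_mean + rng.normal(0.0, 1.0) * noise[1]
            records.append(
                IsotopeRecord(
                    taxon=f"taxon_{t:02d}",
                    site=scenario.baseline.site,
                    guild=guilds[t],
                    layer="pooled",
                    d13c=float(sig[0]),
                    d15n=float(sig[1]),
                    n_pooled=max(1, scenario.samples_per_taxon),
                )
            )
        if scenario.true_tls is not None:
            tl_true = float(tls[t])
        else:
            tl_true = float(
                (mean_sig[1] - scenario.baseline.d15n_sediment)
                / scenario.enrichment_per_level
                + 1.0
            )
        truth_rows.append(
            {
                "taxon": f"taxon_{t:02d}",
                "guild": guilds[t],
                **{f"p_{s.name}": diets[t, j] for j, s in enumerate(scenario.sources)},
                "tl_true": tl_true,
            }
        )
    return records, pd.DataFrame(truth_rows)


def generate_cores(scenario: CommunityScenario) -> pd.DataFrame:
    """Simulate a replicate-core community table.

    Counts per core × taxon × layer are negative-binomial with mean
    ``mean_count_per_core`` (split across layers) and variance
    μ(1 + φμ); ``overdispersion=0`` reproduces the Poisson limit.  Each
    individual's C biomass is lognormal; N biomass follows from the C/N
    ratio.  Setting ``scenario.megafauna`` injects outlier individuals to
    exercise the megafauna screen.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    guilds = scenario.guild_assignment or tuple(
        GUILDS[i % (len(GUILDS) - 1)] for i in range(scenario.n_taxa)
    )
    layers = ("0-5 cm", "5-10 cm")
    rows = []
    for c in range(scenario.n_cores):
        core_id = f"{scenario.baseline.site}-{c + 1:02d}"
        for t in range(scenario.n_taxa):
            for layer, frac in zip(layers, scenario.layer_split):
                m = scenario.mean_count_per_core * frac
                count = int(_draw_count(rng, m, scenario.overdispersion))
                if count == 0:
                    continue
                c_bio = float(
                    np.exp(
                        rng.normal(
                            scenario.biomass_log_mean,
                            scenario.biomass_log_sigma,
                            size=count,
                        )
                    ).sum()
                )
                rows.append(
                    {
                        "core_id": core_id,
                        "site": scenario.baseline.site,
                        "layer": layer,
                        "taxon": f"taxon_{t:02d}",
                        "guild": guilds[t],
                        "count": count,
                        "c_biomass_mg": c_bio,
                        "n_biomass_mg": c_bio / scenario.cn_ratio,
                        "area_m2": scenario.area_m2,
                        "fragment_flag": False,
                    }
                )
    if scenario.megafauna:
        n_out = int(scenario.megafauna.get("n", 3))
        c_each = float(scenario.megafauna.get("c_biomass_mg", 5.0))
        taxon = scenario.megafauna.get("taxon", "megafauna_outlier")
        cores_hit = rng.choice(scenario.n_cores, size=n_out, replace=True)
        for c in cores_hit:
            rows.append(
                {
                    "core_id": f"{scenario.baseline.site}-{c + 1:02d}",
                    "site": scenario.baseline.site,
                    "layer": "0-5 cm",
                    "taxon": taxon,
                    "guild": "FF",
                    "count": 1,
                    "c_biomass_mg": c_each,
                    "n_biomass_mg": c_each / scenario.cn_ratio,
                    "area_m2": scenario.area_m2,
                    "fragment_flag": False,
                }
            )
    from .community import CORE_TABLE_COLUMNS

    return pd.DataFrame(rows, columns=list(CORE_TABLE_COLUMNS))


def _draw_count(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / phi  # var = mean * (1 + phi * mean)
    return int(rng.negative_binomial(r, r / (r + mean)))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name.

    ``table1`` – ``table3`` and ``text_values`` transcribe printed study
    values with provenance columns; ``*_synthetic`` fixtures are
    constructed stand-ins.  ``table3`` keeps its share columns as strings
    because the printed table reports sub-percent shares as ``"<1"``.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    path = resources.files("isotroph").joinpath("fixtures", f"{name}.csv")
    with resources.as_file(path) as p:
        if name == "table3":
            return pd.read_csv(p, dtype=str)
        return pd.read_csv(p)
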