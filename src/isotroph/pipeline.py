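"""Full-analysis orchestration: ingest → correct → mixing → trophic →
community → report, with deterministic seeding and a run manifest.

The manifest records the configuration hash, seed, package/library
versions and a SHA-256 checksum of every output file; it contains no
timestamps, so two runs on the same inputs with the same seed produce
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import composition, densities, exclude_megafauna, read_core_table
from .core import (
    PreservationCorrection,
    TableDialect,
    formalin_correct,
    read_isotope_table,
)
from .mixing import MixingModelSpec, fit_mixing_model, read_sources_table
from .trophic import (
    BaselineSignature,
    BiplotPoint,
    TrophicParams,
    baseline_for_site,
    food_web_length,
    layman_cd,
    layman_nnd,
    tl_class_counts,
    trophic_level,
    reported_trophic_level,
)

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger("isotroph")

_CONFIG_FIELDS = {
    "isotopes",
    "baselines",
    "out_dir",
    "seed",
    "sources",
    "cores",
    "group_by",
    "enrichment_per_level",
    "d13c_offset",
    "d15n_offset",
    "chains",
    "iterations",
    "burn_in",
    "thin",
    "delimiter",
    "verbosity",
}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Validated configuration of one full analysis run."""

    isotopes: str
    baselines: str
    out_dir: str
    seed: int
    sources: str | None = None
    cores: str | None = None
    group_by: str = "guild"
    enrichment_per_level: float = 3.8
    d13c_offset: float = 1.0
    d15n_offset: float = 0.0
    chains: int = 4
    iterations: int = 4000
    burn_in: float = 0.5
    thin: int = 1
    delimiter: str = ","
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PipelineError("config", "seed is mandatory")
        if self.group_by not in ("taxon", "guild"):
            raise PipelineError(
                "config", f"group_by must be 'taxon' or 'guild', got {self.group_by!r}"
            )
        if self.enrichment_per_level <= 0:
            raise PipelineError("config", "enrichment_per_level must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        missing = {"isotopes", "baselines", "out_dir", "seed"} - set(raw)
        if missing:
            raise PipelineError("config", f"missing config key(s): {sorted(missing)}")
        return cls(**raw)


def _read_baselines(path: str, delimiter: str) -> list[BaselineSignature]:
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True)
    required = {"site", "d15n_sediment"}
    if not required <= set(df.columns):
        raise PipelineError(
            "trophic", f"{path}: baseline table needs columns {sorted(required)}"
        )
    return [
        BaselineSignature(
            site=str(r["site"]),
            d15n_sediment=float(r["d15n_sediment"]),
            d13c_sediment=float(r.get("d13c_sediment", float("nan"))),
            sd=float(r.get("d15n_sd", 0.0)),
            n=int(r.get("n", 1)),
        )
        for _, r in df.iterrows()
    ]


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle plus a manifest.

    Returns a dict with the in-memory results keyed by output name.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dialect = TableDialect(delimiter=config.delimiter)
    results: dict = {}
    written: list[Path] = []

    # -- ingest --------------------------------------------------------
    try:
        records = read_isotope_table(config.isotopes, dialect)
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    if not records:
        raise PipelineError("ingest", f"{config.isotopes}: isotope table is empty")
    logger.info("ingest: %d consumer records", len(records))

    # -- preservation correction --------------------------------------
    try:
        correction = PreservationCorrection(config.d13c_offset, config.d15n_offset)
        flagged = [r for r in records if r.preserved_formalin and not r.corrected]
        others = [r for r in records if not (r.preserved_formalin and not r.corrected)]
        records = formalin_correct(flagged, correction) + others
    except Exception as exc:
        raise PipelineError("correct", str(exc)) from exc
    logger.info("correct: %d records corrected", len(flagged))

    # -- trophic metrics -----------------------------------------------
    try:
        baselines = _read_baselines(config.baselines, config.delimiter)
        params = TrophicParams(enrichment_per_level=config.enrichment_per_level)
        tl_rows = []
        for r in records:
            b = baseline_for_site(baselines, r.site)
            tl_rows.append(
                {
                    "taxon": r.taxon,
                    "site": r.site,
                    "guild": r.guild,
                    "d13c": r.d13c,
                    "d15n": r.d15n,
                    "tl": trophic_level(r.d15n, b, params),
                    "tl_reported": reported_trophic_level(r.d15n, b, params),
                }
            )
        tl_table = pd.DataFrame(tl_rows)
        site_rows, class_rows = [], []
        for site, sub in tl_table.groupby("site"):
            points = [
                BiplotPoint(t, x, y)
                for t, x, y in zip(sub["taxon"], sub["d13c"], sub["d15n"])
            ]
            site_rows.append(
                {
                    "site": site,
                    "n_taxa": len(sub),
                    "food_web_length": food_web_length(sub["tl"], params),
                    "layman_cd": layman_cd(points),
                    "layman_nnd": layman_nnd(points) if len(points) > 1 else float("nan"),
                }
            )
            for cls, cnt in tl_class_counts(sub["tl"].tolist()).items():
                class_rows.append({"site": site, "tl_class": cls, "count": cnt})
        results["trophic_levels"] = tl_table
        results["site_metrics"] = pd.DataFrame(site_rows)
        results["tl_classes"] = pd.DataFrame(class_rows)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("trophic", str(exc)) from exc

    # -- mixing model --------------------------------------------------
    if config.sources is not None:
        try:
            sources, tef = read_sources_table(config.sources, config.delimiter)
            spec = MixingModelSpec(sources=sources, tef=tef)
            groups = {}
            for r in records:
                key = (r.site, r.taxon if config.group_by == "taxon" else r.guild)
                groups.setdefault(key, []).append(r)
            diet_rows = []
            for gi, key in enumerate(sorted(groups)):
                site, label = key
                seed = int(
                    np.random.SeedSequence([config.seed, gi]).generate_state(1)[0]
                    % (2**31)
                )
                post = fit_mixing_model(
                    groups[key],
                    spec,
                    chains=config.chains,
                    iterations=config.iterations,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    seed=seed,
                )
                for src, row in post.summaries.iterrows():
                    diet_rows.append(
                        {
                            "site": site,
                            "group": label,
                            "source": src,
                            "mean": row["mean"],
                            "median": row["median"],
                            "ci_low": row.iloc[2],
                            "ci_high": row.iloc[3],
                            "converged": post.diagnostics["converged"],
                            "seed": post.seed,
                        }
                    )
            results["diet_proportions"] = pd.DataFrame(diet_rows)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("mixing", str(exc)) from exc

    # -- community metrics ---------------------------------------------
    if config.cores is not None:
        try:
            cores = read_core_table(config.cores, config.delimiter)
            kept, report = exclude_megafauna(cores)
            summaries, comp_frames = [], []
            for site, sub in kept.groupby("site"):
                summary = densities(sub)
                t = summary.table.reset_index()
                t.insert(0, "site", site)
                summaries.append(t)
                comp = composition(sub, level="taxon").reset_index()
                comp.insert(0, "site", site)
                comp_frames.append(comp)
            results["community_table"] = pd.concat(summaries, ignore_index=True)
            results["composition"] = pd.concat(comp_frames, ignore_index=True)
            results["exclusions"] = pd.DataFrame(
                [
                    {
                        "n_excluded": report["n_excluded"],
                        "c_biomass_per_m2": report["c_biomass_per_m2"],
                        "n_biomass_per_m2": report["n_biomass_per_m2"],
                    }
                ]
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("community", str(exc)) from exc

    # -- report bundle -------------------------------------------------
    for name, frame in results.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)

    config_dict = asdict(config)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "isotroph": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    logger.info("wrote %d outputs to %s", len(written) + 1, out_dir)
    return results
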