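"""Orchestration: two-triangle correlation reports and end-to-end runs.

The report layout mirrors the field's cohort tables: the upper triangle
holds conventional Pearson correlations with two-sided p-values and the
pairwise n, the lower triangle the latent-scale estimates corrected for
censoring and grouping (tetrachoric / polychoric / biserial as the pair of
measurement kinds dictates), printed as ``est ± se (lo to hi)``.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from .latentcorr import LatentCorrEstimate, VariableSpec, fit_latent_correlation
from .mcmc import McmcConfig
from .pathmodel import export_dot, fit_backbone
from .simulate import (
    StageObservation,
    SyntheticConfig,
    Uptake,
    cohort_1990_like,
    generate_cohort,
    uclms_like,
)

__all__ = [
    "MatrixReport",
    "pearson_pairwise",
    "build_matrix_report",
    "run_end_to_end",
    "load_config",
    "load_variable_specs",
    "ConfigError",
    "DataError",
    "EstimationError",
]

log = logging.getLogger("cohortpath")


class ConfigError(ValueError):
    """Bad or missing configuration keys (CLI exit code 2)."""


class DataError(ValueError):
    """Unusable input data (CLI exit code 3)."""


class EstimationError(RuntimeError):
    """Estimation failed irrecoverably (CLI exit code 4)."""


@dataclass
class MatrixReport:
    variables: list[str]
    pearson: dict[tuple[str, str], tuple[float, float, int]] = field(default_factory=dict)
    corrected: dict[tuple[str, str], LatentCorrEstimate | None] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Two-triangle text matrix: Pearson ``r (p, n)`` above the
        diagonal, corrected ``est ± se (lo to hi)`` below, 1 on it."""
        k = len(self.variables)
        cells = [["" for _ in range(k)] for _ in range(k)]
        for i in range(k):
            cells[i][i] = "1"
        for (a, b), entry in self.pearson.items():
            i, j = self.variables.index(a), self.variables.index(b)
            if entry is None:
                cells[i][j] = "n/a"
            else:
                r, p, n = entry
                cells[i][j] = f"{r:.3f} (p={p:.3g}, n={n})"
        for (a, b), est in self.corrected.items():
            i, j = self.variables.index(a), self.variables.index(b)
            cells[j][i] = est.format() if est is not None else "failed"
        return pd.DataFrame(cells, index=self.variables, columns=self.variables)

    def to_json(self) -> str:
        payload = {
            "variables": self.variables,
            "kinds": self.kinds,
            "pearson": [
                {"x": a, "y": b, "r": e[0], "p": e[1], "n": e[2]}
                for (a, b), e in self.pearson.items()
                if e is not None
            ],
            "corrected": [
                {"x": a, "y": b, **est.to_dict()}
                for (a, b), est in self.corrected.items()
                if est is not None
            ],
            "failed_pairs": [
                {"x": a, "y": b}
                for (a, b), est in self.corrected.items()
                if est is None
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MatrixReport":
        d = json.loads(text)
        rep = cls(variables=d["variables"], kinds=d.get("kinds", {}))
        for e in d["pearson"]:
            rep.pearson[(e["x"], e["y"])] = (e["r"], e["p"], e["n"])
        for e in d["corrected"]:
            rep.corrected[(e["x"], e["y"])] = LatentCorrEstimate(
                rho=e["rho"], se=e["se"], ci=tuple(e["ci"]), n_pairs=e["n_pairs"],
                mu=e["mu"], sigma=e["sigma"],
                tau={k: np.asarray(v) for k, v in e["tau"].items()},
                accept_rate=e["accept_rate"], stability_z=e["stability_z"],
                stability_ok=e["stability_ok"], n_dropped=e["n_dropped"],
            )
        for e in d.get("failed_pairs", []):
            rep.corrected[(e["x"], e["y"])] = None
        return rep


def pearson_pairwise(
    table: pd.DataFrame, min_n: int = 10
) -> dict[tuple[str, str], tuple[float, float, int] | None]:
    """Pearson r, two-sided p (t transform) and pairwise-complete n for
    every column pair; pairs below ``min_n`` are marked unavailable."""
    out: dict[tuple[str, str], tuple[float, float, int] | None] = {}
    cols = list(table.columns)
    for a, b in itertools.combinations(cols, 2):
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < max(3, min_n) or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            out[(a, b)] = None
            continue
        r, p = pearsonr(sub[a], sub[b])
        out[(a, b)] = (float(r), float(p), n)
    return out


def build_matrix_report(
    table: pd.DataFrame,
    specs: dict[str, VariableSpec],
    config: McmcConfig | None = None,
    min_n: int = 10,
) -> MatrixReport:
    """Assemble the two-triangle report for all spec'd columns.

    Each pair is dispatched to the unified latent-correlation estimator;
    the pair of measurement kinds alone determines whether the corrected
    value is a censored-normal, polyserial-style, polychoric, tetrachoric
    or biserial correlation.  A failed pair is flagged and the run
    continues.
    """
    config = config or McmcConfig()
    variables = [c for c in table.columns if c in specs]
    rep = MatrixReport(
        variables=variables, kinds={v: specs[v].kind for v in variables}
    )
    rep.pearson = pearson_pairwise(table[variables], min_n=min_n)
    for idx, (a, b) in enumerate(itertools.combinations(variables, 2)):
        sub = table[[a, b]].dropna()
        if len(sub) < min_n:
            rep.corrected[(a, b)] = None
            continue
        try:
            # per-pair deterministic seed derived from the base seed
            pair_cfg = McmcConfig(
                chain_length=config.chain_length,
                estimate_window=config.estimate_window,
                seed=config.seed * 1000 + idx,
                adapt_start_frac=config.adapt_start_frac,
                adapt_interval=config.adapt_interval,
                initial_scale=config.initial_scale,
                delayed_rejection=config.delayed_rejection,
                dr_shrink=config.dr_shrink,
            )
            rep.corrected[(a, b)] = fit_latent_correlation(
                table[a].to_numpy(), table[b].to_numpy(), specs[a], specs[b], pair_cfg
            )
        except (ValueError, RuntimeError) as exc:  # flag and continue
            log.warning("corrected estimate failed for (%s, %s): %s", a, b, exc)
            rep.corrected[(a, b)] = None
    return rep


# ---------------------------------------------------------------------------
# configuration loading

_PRESETS = {"uclms_like": uclms_like, "cohort_1990_like": cohort_1990_like}


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration and check required keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    missing = [k for k in ("cohort",) if k not in cfg]
    if missing:
        raise ConfigError(f"config missing required keys: {missing}")
    return cfg


def _synthetic_config_from(cfg: dict, seed: int) -> SyntheticConfig:
    cohort = cfg["cohort"]
    if isinstance(cohort, str):
        if cohort not in _PRESETS:
            raise ConfigError(
                f"unknown preset {cohort!r}; available: {sorted(_PRESETS)}"
            )
        kwargs = {}
        if "n" in cfg:
            key = "n_entrants" if cohort == "uclms_like" else "n_applicants"
            kwargs[key] = int(cfg["n"])
        return _PRESETS[cohort](seed=seed, **kwargs)
    try:
        observation = {
            k: StageObservation(**v) for k, v in cohort.pop("observation", {}).items()
        }
        uptake = [Uptake(**u) for u in cohort.pop("uptake", [])]
        return SyntheticConfig(**cohort, observation=observation, uptake=uptake, seed=seed)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad cohort configuration: {exc}") from exc


def load_variable_specs(path: str | Path) -> dict[str, VariableSpec]:
    """Read the per-column measurement metadata file (YAML or JSON)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: VariableSpec.from_dict({"name": name, **d}) for name, d in raw.items()}


def _dump_variable_specs(specs: dict[str, VariableSpec], path: Path) -> None:
    payload = {
        name: {k: v for k, v in s.to_dict().items() if k != "name" and v is not None}
        for name, s in specs.items()
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# end-to-end run

def run_end_to_end(config_path: str | Path, seed: int, out_dir: str | Path) -> dict:
    """simulate -> correlate -> path-fit -> export.

    Writes ``cohort.csv``, ``variables.yaml``, ``matrix.csv``,
    ``matrix.json``, ``edges.csv``, ``model.dot`` and
    ``truth_vs_estimate.json`` under ``out_dir``.  Identical config + seed
    give byte-identical outputs.  Returns a manifest of the bundle.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("end-to-end run: config=%s seed=%d out=%s", config_path, seed, out)

    syn = _synthetic_config_from(cfg, seed)
    log.info("simulating cohort: %d applicants, stages %s (seed %d)",
             syn.n_applicants, syn.stages, seed)
    table, specs, truth = generate_cohort(syn)

    table.to_csv(out / "cohort.csv", index=False, float_format="%.6g")
    _dump_variable_specs(specs, out / "variables.yaml")

    mcmc_cfg = McmcConfig(
        chain_length=int(cfg.get("chain_length", 5000)),
        estimate_window=int(cfg.get("estimate_window", 2000)),
        seed=seed,
    )
    log.info("correlation matrix: chain length %d, window %d",
             mcmc_cfg.chain_length, mcmc_cfg.estimate_window)
    try:
        report = build_matrix_report(table[syn.stages], specs, mcmc_cfg,
                                     min_n=int(cfg.get("min_n", 10)))
    except Exception as exc:
        raise EstimationError(f"matrix report failed: {exc}") from exc
    report.to_frame().to_csv(out / "matrix.csv")
    (out / "matrix.json").write_text(report.to_json())

    log.info("path model over %s", syn.stages)
    model = fit_backbone(table, order=syn.stages,
                         threshold=float(cfg.get("path_threshold", 0.05)))
    model.to_frame().to_csv(out / "edges.csv", index=False, float_format="%.6g")
    n_stages = len(syn.stages)
    stage_class = {
        s: ("pre" if i < n_stages // 3 + 1 else
            "medical" if i < 2 * n_stages // 3 + 1 else "postgraduate")
        for i, s in enumerate(syn.stages)
    }
    (out / "model.dot").write_text(export_dot(model, stages=stage_class))

    comparison = {
        "pairs": [
            {
                "x": a, "y": b,
                "true_rho": truth.latent_corr(a, b),
                "estimate": est.rho, "ci": list(est.ci),
                "covered": est.ci[0] <= truth.latent_corr(a, b) <= est.ci[1],
            }
            for (a, b), est in report.corrected.items()
            if est is not None
        ],
        "truth": truth.to_dict(),
        "seed": seed,
    }
    (out / "truth_vs_estimate.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True)
    )
    files = ["cohort.csv", "variables.yaml", "matrix.csv", "matrix.json",
             "edges.csv", "model.dot", "truth_vs_estimate.json"]
    log.info("bundle complete: %s", files)
    return {"out_dir": str(out), "files": files}
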