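"""Result assembly: cost tables, plane/CEAC exports and run manifests.

Renderers never compute: every number in a rendered table comes from a
persisted CSV, and currency formatting (2 dp, thousands separators)
happens only at render time.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import AdjustmentSpec, CEAResult, adjusted_difference, bootstrap_cloud

COST_CATEGORIES = ("service_cost", "medication_cost", "intervention_cost", "total_nhs_pss")


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percentage, rounded half-up (125/162 -> 77)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def summarise_costs(
    table: pd.DataFrame,
    cost_columns: Sequence[str],
    covariates: Sequence[str] = (),
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Disaggregated cost table: per-arm means and adjusted differences.

    Rows are cost categories (the listed columns plus their total); group
    means use complete cases for each category, and the between-arm
    difference is covariate-adjusted with a percentile-bootstrap 95% CI.
    Imputation happens upstream at the aggregate level, so disaggregated
    rows are complete-case by construction.
    """
    for armval in (0, 1):
        if not (table["arm"] == armval).any():
            raise ValueError(f"no participants in arm {armval}")
    work = table.copy()
    cols = list(cost_columns)
    work["total"] = work[cols].sum(axis=1)
    rows = []
    for cat in cols + ["total"]:
        sub = work.dropna(subset=[cat])
        covs = tuple(c for c in covariates if c in sub.columns)
        spec = AdjustmentSpec(cat, covs)
        diff, _ = adjusted_difference(sub, spec)
        cloud = bootstrap_cloud([sub], spec, spec, B=B, seed=seed)
        lo, hi = np.percentile(cloud.delta_cost, [2.5, 97.5])
        rows.append(
            {
                "category": cat,
                "mean_control": float(sub.loc[sub["arm"] == 0, cat].mean()),
                "mean_intervention": float(sub.loc[sub["arm"] == 1, cat].mean()),
                "adjusted_difference": diff,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_complete": len(sub),
            }
        )
    return pd.DataFrame(rows)


def format_gbp(value: float) -> str:
    return f"£{value:,.2f}"


def export_plots(result: CEAResult, outdir, stem: str = "cea") -> dict[str, str]:
    """Write the CE plane and CEAC as CSV plus matplotlib figures.

    The CSVs carry exactly the plotted numbers, so every figure is
    reproducible from its CSV alone.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    plane = result.cloud.to_frame()
    paths["plane_csv"] = str(outdir / f"{stem}_plane.csv")
    plane.to_csv(paths["plane_csv"], index=False)

    ceac_frame = pd.DataFrame(
        {"lambda": list(result.ceac), "probability": list(result.ceac.values())}
    )
    paths["ceac_csv"] = str(outdir / f"{stem}_ceac.csv")
    ceac_frame.to_csv(paths["ceac_csv"], index=False)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["delta_effect"], plane["delta_cost"], s=2, alpha=0.3)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel(f"Incremental effect ({result.effect_label})")
    ax.set_ylabel("Incremental cost (£)")
    ax.set_title("Cost-effectiveness plane")
    paths["plane_png"] = str(outdir / f"{stem}_plane.png")
    fig.savefig(paths["plane_png"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_frame["lambda"], ceac_frame["probability"])
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"Willingness to pay (£ per {result.effect_label})")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    paths["ceac_png"] = str(outdir / f"{stem}_ceac.png")
    fig.savefig(paths["ceac_png"], dpi=120)
    plt.close(fig)
    return paths


@dataclass
class RunManifest:
    """Audit record binding configuration, seeds and inputs to outputs."""

    config_hash: str
    seed: int
    package_version: str
    input_digests: dict[str, str]
    timestamp: str

    @classmethod
    def create(
        cls, config: Mapping, seed: int, input_paths: Mapping[str, str] | None = None
    ) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        digests = {}
        for name, path in (input_paths or {}).items():
            digests[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            package_version=__version__,
            input_digests=digests,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
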