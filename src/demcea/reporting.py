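"""Publication-style table rendering and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .parameters import ModelParameters, params_to_dict

__all__ = ["RunManifest", "render_results_table", "format_icer_cell"]


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every results file."""

    config_path: str
    parameter_hash: str
    command: str
    seed: int | None
    timestamp: str
    package_version: str

    @classmethod
    def create(
        cls, config_path: str | Path, params: ModelParameters, command: str, seed: int | None = None
    ) -> "RunManifest":
        blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
        return cls(
            config_path=str(config_path),
            parameter_hash=hashlib.sha256(blob).hexdigest()[:16],
            command=command,
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            package_version=__version__,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def format_icer_cell(row: pd.Series) -> str:
    if row["verdict"] == "dominant":
        return "Intervention dominates"
    if row["verdict"] == "dominated":
        return "Dominated"
    if row["verdict"] == "zero_qaly_diff":
        return "—"
    return f"£{row['icer']:,.0f}"


def render_results_table(results: pd.DataFrame) -> str:
    """Format a scenario-suite results frame in the published table layout.

    Costs are rounded to the pound with thousands separators, per-person
    QALYs to 3 decimals, net QALYs to 4 decimals; ICERs (computed upstream
    from unrounded values) to the pound; dominant cells read
    "Intervention dominates".
    """
    if results.empty:
        return ""
    blocks = []
    group_cols = ["horizon_years", "intervention_cost", "subgroup_only", "perspective"]
    for (horizon, cost, subgroup, perspective), grp in results.groupby(group_cols, sort=False):
        header = (
            f"{horizon:g}-year horizon, intervention £{cost:,.0f}"
            + (", moderate-subgroup effect" if subgroup else "")
            + (", societal perspective" if perspective == "societal" else "")
        )
        first = grp.iloc[0]
        lines = [
            header,
            f"{'Effect':>8} {'Cost/person':>14} {'Net cost':>10} "
            f"{'QALYs/person':>13} {'Net QALYs':>10} {'ICER':>24}",
            f"{'0%':>8} {'£' + format(round(first['control_cost_per_person']), ','):>14} "
            f"{'—':>10} {first['control_qalys_per_person']:>13.3f} {'—':>10} {'—':>24}",
        ]
        for _, row in grp.iterrows():
            lines.append(
                f"{row['effect'] * 100:>7.3g}% "
                f"{'£' + format(round(row['cost_per_person']), ','):>14} "
                f"{'£' + format(round(row['net_cost']), ','):>10} "
                f"{row['qalys_per_person']:>13.3f} "
                f"{row['net_qalys']:>10.4f} "
                f"{format_icer_cell(row):>24}"
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
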