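"""Report bundles: reach + scenario range + triangulation, written stably.

Reports are deterministic: for a fixed bundle the JSON and CSV outputs are
byte-identical run to run (sorted keys, fixed number formatting), so that
archived reports can be diffed.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, model_validator

from . import __version__
from .config import ProductConfig
from .engine import ReachResult
from .pipeline import coverage_estimate, estimate
from .rounding import FULL_PRECISION, RoundingPolicy
from .scenarios import ScenarioRange, ScenarioSpec, run_scenarios


class Triangulation(BaseModel):
    """Supply-route vs coverage-route estimates of the same reach.

    ``ratio`` is supply-based ÷ coverage-based; values far from 1 flag a
    discrepancy between routine monitoring data and survey data.
    """

    coverage_based: int
    supply_based: int
    ratio: Optional[float] = None

    @model_validator(mode="after")
    def _fill_ratio(self) -> "Triangulation":
        if self.ratio is None and self.coverage_based > 0:
            object.__setattr__(
                self, "ratio", self.supply_based / self.coverage_based
            )
        return self


class Provenance(BaseModel):
    config_hash: str
    policy: str
    tool_version: str = __version__


class ReportBundle(BaseModel):
    reach: ReachResult
    scenario_range: Optional[ScenarioRange] = None
    triangulation: Optional[Triangulation] = None
    provenance: Provenance


def config_hash(config: ProductConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_bundle(
    config: ProductConfig,
    policy: RoundingPolicy = FULL_PRECISION,
    scenarios: Optional[list[ScenarioSpec]] = None,
) -> ReportBundle:
    """Run the full pipeline and assemble a report bundle.

    Triangulation is included only when both estimation routes are
    computable, i.e. the config has a coverage block *and* a supply route.
    """
    reach = estimate(config, policy)
    triangulation = None
    has_supply_route = config.supply is not None or config.components is not None
    if config.coverage is not None and has_supply_route:
        cov = coverage_estimate(config)
        triangulation = Triangulation(
            coverage_based=cov.total_reach, supply_based=reach.total_reach
        )
    scenario_range = (
        run_scenarios(config, scenarios, policy) if scenarios else None
    )
    return ReportBundle(
        reach=reach,
        scenario_range=scenario_range,
        triangulation=triangulation,
        provenance=Provenance(
            config_hash=config_hash(config), policy=policy.mode.value
        ),
    )


def _fmt(value, ndigits: int) -> str:
    return f"{float(value):.{ndigits}f}"


def _bundle_to_jsonable(bundle: ReportBundle) -> dict:
    data = bundle.model_dump(mode="json")
    tri = data.get("triangulation")
    if tri and tri.get("ratio") is not None:
        tri["ratio"] = float(_fmt(tri["ratio"], 4))
    return data


def write_report(
    bundle: ReportBundle, path: Union[str, Path], format: str = "json"
) -> None:
    """Write the bundle as sorted-key JSON or a flat CSV table."""
    path = Path(path)
    if format == "json":
        text = json.dumps(_bundle_to_jsonable(bundle), sort_keys=True, indent=2)
        path.write_text(text + "\n")
    elif format == "csv":
        path.write_text(render_csv(bundle))
    else:
        raise ValueError(f"unknown report format {format!r}")


def render_csv(bundle: ReportBundle) -> str:
    """Flat table: one row for the total, then one per segment/subgroup."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["section", "name", "reach", "formula", "policy"])
    r = bundle.reach
    policy = bundle.provenance.policy
    writer.writerow(["total", "", r.total_reach, r.formula_used.value, policy])
    for name, count in r.segment_reach.items():
        writer.writerow(["segment", name, count, "", ""])
    for name, count in r.component_reach.items():
        writer.writerow(["component", name, count, "", ""])
    for name, count in r.subgroup_reach.items():
        writer.writerow(["subgroup", name, count, "", ""])
    if bundle.scenario_range is not None:
        sr = bundle.scenario_range
        writer.writerow(["scenario_low", sr.low_scenario, sr.low_reach, "", ""])
        writer.writerow(["scenario_high", sr.high_scenario, sr.high_reach, "", ""])
    return buf.getvalue()
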