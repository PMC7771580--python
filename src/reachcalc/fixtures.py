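"""Packaged example inputs: the Brazil fortified-rice case.

The config ships with the package; the monthly supply ledger is *synthetic*
— the project's monthly sales breakdown was never published, so
:func:`write_brazil_fixture` spreads the period total uniformly across the
27 months (integer kilograms, last month absorbing the remainder) purely to
exercise the ledger-ingestion path. Its period total is exact.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import yaml

from .config import ProductConfig

BRAZIL_TOTAL_KG = 11_174_560  # 11,174.56 metric tons


def brazil_config() -> ProductConfig:
    """The packaged Brazil fortified-rice config."""
    text = (
        resources.files("reachcalc").joinpath("fixtures/brazil.yaml").read_text()
    )
    return ProductConfig.model_validate(yaml.safe_load(text))


def write_brazil_fixture(out_dir: str | Path) -> tuple[Path, Path]:
    """Emit the Brazil config plus a synthetic monthly supply ledger.

    Returns (config path, ledger path). The ledger is one row per month,
    dated the first of the month, in kilograms; rows sum exactly to the
    period total of 11,174.56 MT.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_path = out_dir / "brazil_fortified_rice.yaml"
    text = (
        resources.files("reachcalc").joinpath("fixtures/brazil.yaml").read_text()
    )
    config_path.write_text(text)

    config = brazil_config()
    months = config.period.months()
    per_month = BRAZIL_TOTAL_KG // len(months)
    remainder = BRAZIL_TOTAL_KG - per_month * len(months)
    ledger_path = out_dir / "brazil_supply_ledger_synthetic.csv"
    with ledger_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["date", "region", "quantity", "unit"])
        for i, month in enumerate(months):
            qty = per_month + (remainder if i == len(months) - 1 else 0)
            writer.writerow([f"{month}-01", "BR", qty, "kg"])
    return config_path, ledger_path
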