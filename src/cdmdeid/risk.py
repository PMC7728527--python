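"""Prosecutor-model re-identification risk metrics.

The prosecutor attacker already knows their target is in the dataset, so the
probability of re-identifying a record in an equivalence class of size *s*
is ``1/s``.  Three summary figures are reported per dataset:

* **records at risk** — percentage of records whose risk strictly exceeds
  the configured threshold (default 20%);
* **highest risk** — the maximum per-record risk, ``100 / min class size``;
* **success rate** — the mean per-record risk, i.e. the expected fraction of
  records an attacker re-identifies on average.  Since each class of size
  *s* contributes *s* records of risk ``1/s``, this equals
  ``100 * n_classes / n_records`` — which is also the marketer-model success
  rate under the full-population assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable

from .errors import ConfigError
from .privacy import EquivalenceClass


@dataclass(frozen=True)
class RiskReport:
    """Prosecutor-risk summary for one partition (all percentages in [0, 100])."""

    records_at_risk: float
    highest_risk: float
    success_rate: float
    n_records: int
    n_classes: int
    threshold: float

    @property
    def marketer_success_rate(self) -> float:
        """Marketer-model success under the full-population assumption."""
        return self.success_rate

    def to_dict(self) -> dict:
        return asdict(self)


def prosecutor_risk(classes: Iterable[EquivalenceClass], threshold: float = 0.2) -> RiskReport:
    """Compute the prosecutor-risk report for a partition.

    ``threshold`` is on the risk scale (0, 1]; a record counts as at risk when
    its risk is strictly greater, so after k-anonymity enforcement a threshold
    of ``1/k`` yields exactly zero records at risk.  An empty partition yields
    a zeroed report with ``n_records = 0``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError("risk threshold must lie in (0, 1]")
    sizes = [c.size for c in classes]
    if not sizes:
        return RiskReport(0.0, 0.0, 0.0, 0, 0, threshold)
    n = sum(sizes)
    n_classes = len(sizes)
    at_risk = sum(s for s in sizes if 1.0 / s > threshold)
    return RiskReport(
        records_at_risk=100.0 * at_risk / n,
        highest_risk=100.0 / min(sizes),
        success_rate=100.0 * n_classes / n,
        n_records=n,
        n_classes=n_classes,
        threshold=threshold,
    )


def format_percentage(value: float) -> str:
    """Render a percentage the way the risk tables print it.

    Two-decimal rounding with trailing zeros trimmed ("25", "0.1", "33.33");
    a strictly positive value that rounds below 0.01 prints as "<0.01"; an
    exact zero prints "0".
    """
    if value == 0:
        return "0"
    if 0 < value and round(value, 2) < 0.01:
        return "<0.01"
    s = f"{value:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def format_report(report: RiskReport, as_json: bool = False) -> str:
    """Text (or JSON) rendering of a risk report."""
    if as_json:
        d = report.to_dict()
        d["rendered"] = {
            "records_at_risk": format_percentage(report.records_at_risk),
            "highest_risk": format_percentage(report.highest_risk),
            "success_rate": format_percentage(report.success_rate),
        }
        return json.dumps(d, indent=2)
    return (
        f"records at risk: {format_percentage(report.records_at_risk)}%  "
        f"highest risk: {format_percentage(report.highest_risk)}%  "
        f"success rate: {format_percentage(report.success_rate)}%  "
        f"(n={report.n_records}, classes={report.n_classes}, "
        f"threshold={report.threshold:g})"
    )
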