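"""Regional dose metrics: deposition fractions, film doses, enhancement.

Deposition fraction (DF) of a region is the liquid volume residing there
divided by the *applied* dose, as a percentage — vestibule waste counts
against the delivered fraction, and escaped/expired liquid is reported
separately so the accounting closes to 100%.  Volume weighting keeps the
metrics meaningful for polydisperse sprays (identical to droplet counting
for monodisperse ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nasospray.geometry import LabeledSurfaceMesh, Region, ALL_REGIONS
from nasospray.spray import DropletSet, ESCAPED, EXPIRED, ACTIVE
from nasospray.film import FilmState


class DoseError(ValueError):
    """Invalid dose-metric inputs."""


@dataclass
class RegionalDoseReport:
    """Per-region deposition fractions for one configuration."""

    df_pct: dict                    # region name -> % of applied dose
    escaped_pct: float
    expired_pct: float
    applied_dose_ml: float
    config_digest: str = ""

    def df(self, region: Region | str) -> float:
        key = region.value if isinstance(region, Region) else region
        return self.df_pct[key]

    def total_deposited_pct(self) -> float:
        return float(sum(self.df_pct.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "df_pct": v} for k, v in self.df_pct.items()]
        rows.append({"region": "ESCAPED", "df_pct": self.escaped_pct})
        rows.append({"region": "EXPIRED", "df_pct": self.expired_pct})
        return pd.DataFrame(rows)


def initial_DF(records: pd.DataFrame, droplets: DropletSet,
               mesh: LabeledSurfaceMesh, applied_dose_ml: float,
               config_digest: str = "") -> RegionalDoseReport:
    """Volume-weighted initial deposition fractions per region."""
    dose_m3 = applied_dose_ml * 1e-6
    if dose_m3 <= 0:
        raise DoseError("applied dose must be positive")
    df = {r.value: 0.0 for r in ALL_REGIONS}
    if len(records):
        per_region = records.groupby("region")["volume_m3"].sum()
        for region, vol in per_region.items():
            df[region] = 100.0 * float(vol) / dose_m3
    escaped = 100.0 * float(droplets.weight[droplets.status == ESCAPED].sum()) / dose_m3
    expired = 100.0 * float(
        droplets.weight[(droplets.status == EXPIRED)
                        | (droplets.status == ACTIVE)].sum()) / dose_m3
    return RegionalDoseReport(df_pct=df, escaped_pct=escaped,
                              expired_pct=expired,
                              applied_dose_ml=applied_dose_ml,
                              config_digest=config_digest)


def film_region_dose(state: FilmState, mesh: LabeledSurfaceMesh,
                     applied_dose_ml: float) -> dict:
    """Film volume per region as % of applied dose: sum(h·area) / dose."""
    dose_m3 = applied_dose_ml * 1e-6
    if dose_m3 <= 0:
        raise DoseError("applied dose must be positive")
    vols = state.h * mesh.face_area
    out = {}
    for r in ALL_REGIONS:
        out[r.value] = 100.0 * float(vols[mesh.faces_in_region(r)].sum()) / dose_m3
    return out


def enhancement_factor(post_df_pct: float, pre_df_pct: float) -> float:
    """Fold change post/pre; NaN (undefined) when the pre dose is zero."""
    if pre_df_pct < 0:
        raise DoseError("pre-migration DF must be non-negative")
    if pre_df_pct == 0.0:
        return float("nan")
    return post_df_pct / pre_df_pct


def relative_change(after_pct: float, before_pct: float) -> float:
    """Signed percent change (after - before)/before · 100."""
    if before_pct <= 0:
        raise DoseError("baseline value must be positive")
    return (after_pct - before_pct) / before_pct * 100.0


def round_report(value: float, kind: str = "df") -> float:
    """House rounding: DFs and factors to 2 decimals, percent changes to
    integers."""
    if kind in ("df", "factor"):
        return round(value, 2)
    if kind == "change":
        return float(round(value))
    raise DoseError(f"unknown report kind {kind!r}")


def dose_response_sweep(doses_ml, pipeline, ol_overflow_tol: float = 0.05
                        ) -> pd.DataFrame:
    """Run the full pipeline at each applied dose; tabulate regional doses.

    ``pipeline`` is a callable dose_ml -> (initial RegionalDoseReport,
    post-migration film fractions dict).  The returned long-format table has
    columns ``dose_ml, region, volume_m3, df_pct, phase`` with phase in
    {initial, film}.  The attribute ``overflow_onset_ml`` on the frame's
    ``attrs`` records the first dose whose olfactory film volume exceeds the
    olfactory initial deposit by more than ``ol_overflow_tol`` (relative),
    or None.
    """
    rows = []
    onset = None
    for dose in doses_ml:
        if dose <= 0:
            raise DoseError("doses must be positive")
        report, film_fracs = pipeline(dose)
        for region, df in report.df_pct.items():
            rows.append(dict(dose_ml=dose, region=region,
                             volume_m3=df / 100.0 * dose * 1e-6,
                             df_pct=df, phase="initial"))
        for region, df in film_fracs.items():
            rows.append(dict(dose_ml=dose, region=region,
                             volume_m3=df / 100.0 * dose * 1e-6,
                             df_pct=df, phase="film"))
        ol0 = report.df_pct[Region.OL.value]
        ol1 = film_fracs[Region.OL.value]
        if onset is None and ol1 > ol0 * (1.0 + ol_overflow_tol) + 1e-12:
            onset = dose
    table = pd.DataFrame(rows)
    table.attrs["overflow_onset_ml"] = onset
    return table


def select_optimal(reports: dict) -> list:
    """Rank configurations for olfactory delivery.

    Lexicographic: highest olfactory DF, then highest superior-meatus DF,
    then lowest vestibule waste.  ``reports`` maps a label to a
    :class:`RegionalDoseReport`; returns labels best-first (sorted stably,
    so the ranking is a total preorder independent of input order).
    """
    if not reports:
        raise DoseError("need at least one candidate report")
    def key(item):
        label, r = item
        return (-r.df(Region.OL), -r.df(Region.SM), r.df(Region.VEST), label)
    return [label for label, _ in sorted(reports.items(), key=key)]
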