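"""Margins of safety: POD relative to human serum Cmax.

MOS_nominal = POD_nominal / Cmax_total compares the applied in vitro POD to
the highest total drug concentration measured in human serum.  MOS_free
repeats the comparison on the free-concentration scale:

    MOS_free = (POD_nominal × fub_media) / (Cmax_total × fub_plasma)

so that differences in binding between culture medium and plasma are
accounted for.  A right-censored POD ("> 300 µM") yields a lower-bound MOS,
never a point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._censored import CensoredValue, as_censored

__all__ = ["MosValue", "mos_nominal", "mos_free", "select_cmax", "mos_table"]


@dataclass(frozen=True)
class MosValue:
    """A margin of safety; ``is_lower_bound`` marks censored-POD results."""

    value: float
    is_lower_bound: bool = False

    def __str__(self) -> str:
        return f"> {self.value:g}" if self.is_lower_bound else f"{self.value:g}"


def mos_nominal(pod_nominal: float | CensoredValue, cmax_total: float) -> MosValue:
    """POD / Cmax on the nominal (applied-concentration) scale."""
    if cmax_total <= 0:
        raise ValueError(f"cmax_total must be > 0, got {cmax_total}")
    pod = as_censored(pod_nominal)
    return MosValue(pod.value / cmax_total, is_lower_bound=pod.censored)


def mos_free(
    pod_nominal: float | CensoredValue,
    fub_media: float,
    cmax_total: float,
    fub_plasma: float,
) -> MosValue:
    """POD / Cmax on the free-concentration scale.

    Equals mos_nominal × (fub_media / fub_plasma) for uncensored PODs; a
    medium less binding than plasma (fub_media > fub_plasma) therefore
    raises the margin.
    """
    if not 0 < fub_media <= 1:
        raise ValueError(f"fub_media must be in (0, 1], got {fub_media}")
    if not 0 < fub_plasma <= 1:
        raise ValueError(f"fub_plasma must be in (0, 1], got {fub_plasma}")
    if cmax_total <= 0:
        raise ValueError(f"cmax_total must be > 0, got {cmax_total}")
    pod = as_censored(pod_nominal)
    return MosValue(
        (pod.value * fub_media) / (cmax_total * fub_plasma),
        is_lower_bound=pod.censored,
    )


def select_cmax(cmax_min: float, cmax_max: float, basis: str = "max") -> float:
    """Pick the Cmax to divide by when a range was reported.

    The default ``max`` end is the conservative choice (smallest MOS);
    ``min`` and ``mid`` are available alternatives.
    """
    if not 0 < cmax_min <= cmax_max:
        raise ValueError(f"need 0 < cmax_min <= cmax_max, got ({cmax_min}, {cmax_max})")
    if basis == "max":
        return cmax_max
    if basis == "min":
        return cmax_min
    if basis == "mid":
        return 0.5 * (cmax_min + cmax_max)
    raise ValueError(f"unknown cmax basis {basis!r}; use 'min', 'max' or 'mid'")


def mos_table(
    pod_table: pd.DataFrame,
    annotations: pd.DataFrame,
    fub_media_by_source: dict[str, dict[str, float]] | dict[str, float],
    fub_plasma_by_drug: dict[str, float],
    cmax_basis: str = "max",
    pod_metric: str = "ec50",
    aggregate_min_pod: bool = False,
) -> pd.DataFrame:
    """Per-(cell source, drug) nominal and free MOS from a POD table.

    ``fub_media_by_source`` maps cell_source → fub_media (a single float if
    the same medium chemistry applies to every drug, or a per-drug dict).
    With ``aggregate_min_pod`` the most sensitive (minimum) POD across cell
    sources is used for every drug, preferring uncensored PODs.
    """
    pod_col, cens_col = f"{pod_metric}_pod_uM", f"{pod_metric}_censored"
    ann = annotations.set_index("drug")

    table = pod_table
    if aggregate_min_pod:
        rows = []
        for drug, grp in pod_table.groupby("drug", sort=True):
            unc = grp[~grp[cens_col]]
            pick = (unc if not unc.empty else grp).nsmallest(1, pod_col).iloc[0].copy()
            pick["cell_source"] = "min-across-sources"
            rows.append(pick)
        table = pd.DataFrame(rows)

    out = []
    for row in table.itertuples():
        drug = row.drug
        if drug not in ann.index:
            raise KeyError(f"no annotation for drug {drug!r}")
        cmax = select_cmax(
            float(ann.loc[drug, "cmax_min_uM"]), float(ann.loc[drug, "cmax_max_uM"]), cmax_basis
        )
        fm = fub_media_by_source[row.cell_source] if row.cell_source in fub_media_by_source else None
        if isinstance(fm, dict):
            fm = fm[drug]
        if fm is None:
            raise KeyError(f"no fub_media for cell source {row.cell_source!r}")
        fp = fub_plasma_by_drug[drug]
        pod = CensoredValue(getattr(row, pod_col), bool(getattr(row, cens_col)))
        mn = mos_nominal(pod, cmax)
        mf = mos_free(pod, fm, cmax, fp)
        out.append(
            {
                "cell_source": row.cell_source,
                "drug": drug,
                "cmax_basis_uM": cmax,
                "fub_media": fm,
                "fub_plasma": fp,
                "mos_nominal": mn.value,
                "mos_free": mf.value,
                "is_lower_bound": mn.is_lower_bound,
            }
        )
    return pd.DataFrame(out)
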