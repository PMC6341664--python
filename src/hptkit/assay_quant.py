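"""Phosphotransfer gel quantification: percent-of-wild-type with replicates.

Band intensities from a phosphorimaged SDS-PAGE gel enter as a table of
(label, replicate, intensity). Within each replicate every lane is
normalised to that replicate's reference lane (the wild-type protein),
then the per-replicate percentages are averaged across replicates; the
spread is the sample (n-1) standard deviation. Densitometry itself
(image -> intensity) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class GelLane:
    label: str
    replicate: int
    intensity: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative intensity for lane {self.label!r}")


@dataclass
class RelativeActivity:
    label: str
    mean_percent: float
    sd_percent: float  # NaN when n == 1
    n: int


def _as_frame(lanes) -> pd.DataFrame:
    if isinstance(lanes, pd.DataFrame):
        df = lanes.copy()
        if "background" not in df.columns:
            df["background"] = 0.0
        missing = {"label", "replicate", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"lane table missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [(l.label, l.replicate, l.intensity, l.background) for l in lanes],
            columns=["label", "replicate", "intensity", "background"],
        )
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in lane table")
    return df


def percent_of_wildtype(lanes, reference_label: str = "WT") -> list[RelativeActivity]:
    """Per-replicate normalisation to the reference lane, then mean ± SD.

    Each replicate must contain exactly one reference lane with positive
    (background-corrected) intensity. An optional per-lane background is
    subtracted before normalisation (clipped at zero).
    """
    df = _as_frame(lanes)
    df["signal"] = (df["intensity"] - df["background"]).clip(lower=0.0)

    percents: dict[str, list[float]] = {}
    for rep, grp in df.groupby("replicate", sort=True):
        ref = grp[grp["label"] == reference_label]
        if ref.empty:
            raise ValueError(
                f"replicate {rep!r} has no reference lane {reference_label!r}"
            )
        if len(ref) > 1:
            raise ValueError(
                f"replicate {rep!r} has {len(ref)} reference lanes "
                f"{reference_label!r}; expected one"
            )
        ref_signal = float(ref["signal"].iloc[0])
        if ref_signal <= 0:
            raise ValueError(f"replicate {rep!r}: reference intensity is zero")
        for _, row in grp.iterrows():
            percents.setdefault(row["label"], []).append(
                100.0 * row["signal"] / ref_signal
            )

    out = []
    for label in df["label"].drop_duplicates():
        vals = pd.Series(percents[label], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        out.append(RelativeActivity(label, float(vals.mean()), sd, len(vals)))
    return out


def activity_table(activities: list[RelativeActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.label, a.mean_percent, a.sd_percent, a.n) for a in activities],
        columns=["label", "mean_percent", "sd_percent", "n"],
    )
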