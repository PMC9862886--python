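"""Statistical battery and report tables.

Implements Dice agreement between label volumes, paired mean-difference
comparisons (two-sided 95% CI, paired t-test, Pearson correlation),
early-vs-advanced Mann-Whitney U comparisons with medians/IQRs, and the
CSV/JSON report assembly. All tests are two-sided at alpha = 0.05; no
multiple-testing correction is applied (deliberately — recorded in the
report metadata rather than silently added).

Conventions fixed here: sample SD uses the n-1 denominator; IQR = Q3 - Q1
with linear-interpolation quantiles; Dice of two empty masks is 1 and of
one empty mask is 0; Mann-Whitney uses the exact null when
min(n1, n2) <= 8 and there are no ties, otherwise the tie- and
continuity-corrected normal approximation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mask_io import LabelVolume

__all__ = [
    "ALPHA",
    "DiceResult",
    "PairedComparison",
    "GroupComparison",
    "dice",
    "dice_masks",
    "vector_with_moments",
    "paired_comparison",
    "group_comparison",
    "correlation_table",
    "summary_table",
    "paired_table",
    "group_table",
    "build_report",
]

ALPHA = 0.05
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class DiceResult:
    dice_necrotic: float
    dice_unaffected: float


@dataclass(frozen=True)
class PairedComparison:
    n: int
    mean_diff: float
    sd_diff: float
    ci95: tuple[float, float]
    t_stat: float
    p_t: float
    pearson_r: float
    p_r: float
    degenerate: bool = False


@dataclass(frozen=True)
class GroupComparison:
    n_early: int
    n_advanced: int
    median_early: float
    iqr_early: float
    median_advanced: float
    iqr_advanced: float
    u_stat: float
    p_u: float
    method: str


def dice_masks(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); 1 for empty-vs-empty, 0 for
    empty-vs-nonempty."""
    na, nb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / (na + nb)


def dice(a: LabelVolume, b: LabelVolume) -> DiceResult:
    """Per-label Dice agreement between two same-grid segmentations."""
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    return DiceResult(
        dice_necrotic=dice_masks(a.labels == 2, b.labels == 2),
        dice_unaffected=dice_masks(a.labels == 1, b.labels == 1),
    )


def vector_with_moments(n: int, mean: float, sd: float, seed: int = 0) -> np.ndarray:
    """A length-``n`` vector with *exactly* the given sample mean and SD
    (n-1 denominator); useful for reconstructing published summary rows."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = z - z.mean()
    s = z.std(ddof=1)
    if s == 0:  # astronomically unlikely; regenerate deterministically
        z = np.linspace(-1, 1, n)
        z = z - z.mean()
        s = z.std(ddof=1)
    return mean + (sd / s) * z


def paired_comparison(x: Sequence[float], y: Sequence[float]) -> PairedComparison:
    """Paired difference x - y: mean, SD, 95% CI, paired t, Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("paired comparison needs n >= 3")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = False
    if sd == 0.0:
        ci = (mean, mean)
        if mean == 0.0:
            t_stat, p_t = 0.0, 1.0
        else:
            t_stat, p_t = float("inf"), 0.0
            degenerate = True
    else:
        se = sd / np.sqrt(n)
        tq = float(sps.t.ppf(1.0 - ALPHA / 2.0, n - 1))
        ci = (mean - tq * se, mean + tq * se)
        t_stat = mean / se
        p_t = 2.0 * float(sps.t.sf(abs(t_stat), n - 1))
    if np.std(x) == 0 or np.std(y) == 0:
        r, p_r = float("nan"), float("nan")
        degenerate = True
    else:
        r, p_r = sps.pearsonr(x, y)
    return PairedComparison(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        ci95=(float(ci[0]), float(ci[1])),
        t_stat=float(t_stat),
        p_t=float(p_t),
        pearson_r=float(r),
        p_r=float(p_r),
        degenerate=degenerate,
    )


def _iqr(v: np.ndarray) -> float:
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    return float(q3 - q1)


def group_comparison(values: Sequence[float], groups: Sequence[str]) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of early vs advanced cases.

    ``groups`` holds ``"early"``/``"advanced"`` flags aligned with
    ``values``; the U statistic is reported for the early group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    early = values[groups == "early"]
    advanced = values[groups == "advanced"]
    if len(early) == 0 or len(advanced) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(values)) < len(values)
    exact = min(len(early), len(advanced)) <= EXACT_MWU_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        early,
        advanced,
        alternative="two-sided",
        method=method,
        use_continuity=True,
    )
    return GroupComparison(
        n_early=len(early),
        n_advanced=len(advanced),
        median_early=float(np.median(early)),
        iqr_early=_iqr(early),
        median_advanced=float(np.median(advanced)),
        iqr_advanced=_iqr(advanced),
        u_stat=float(res.statistic),
        p_u=float(res.pvalue),
        method=method,
    )


# -- table assembly -------------------------------------------------------
# All table builders take a tidy per-case frame with columns:
#   case_id, group, source, <parameter columns...>, kerboul_modified

PARAMETERS = (
    "necrotic_volume",
    "unaffected_volume",
    "pct_necrotic_volume",
    "necrotic_surface",
    "head_surface",
    "pct_necrotic_surface",
)

KERBOUL_PARAMETERS = (
    "necrotic_volume",
    "pct_necrotic_volume",
    "necrotic_surface",
    "pct_necrotic_surface",
)


def summary_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-source mean, SD and range for each parameter."""
    rows = []
    for param in PARAMETERS + ("kerboul_modified",):
        for source, sub in df.groupby("source", sort=True):
            v = sub[param].to_numpy(dtype=float)
            rows.append(
                {
                    "parameter": param,
                    "source": source,
                    "n": len(v),
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                    "min": v.min(),
                    "max": v.max(),
                }
            )
    return pd.DataFrame(rows)


def paired_table(df: pd.DataFrame, source_a: str, source_b: str) -> pd.DataFrame:
    """Paired comparison (a - b) per parameter, aligned by case_id."""
    a = df[df["source"] == source_a].set_index("case_id").sort_index()
    b = df[df["source"] == source_b].set_index("case_id").sort_index()
    common = a.index.intersection(b.index)
    rows = []
    for param in PARAMETERS:
        if len(common) < 3:
            rows.append({"parameter": param, "n": len(common), "note": "insufficient-n"})
            continue
        pc = paired_comparison(a.loc[common, param], b.loc[common, param])
        rows.append(
            {
                "parameter": param,
                "n": pc.n,
                "mean_diff": pc.mean_diff,
                "sd_diff": pc.sd_diff,
                "ci95_lower": pc.ci95[0],
                "ci95_upper": pc.ci95[1],
                "p_value": pc.p_t,
                "pearson_r": pc.pearson_r,
                "p_correlation": pc.p_r,
                "note": "degenerate" if pc.degenerate else "",
            }
        )
    return pd.DataFrame(rows)


def group_table(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Early-vs-advanced comparison per parameter for one source."""
    sub = df[df["source"] == source]
    rows = []
    for param in ("kerboul_modified",) + PARAMETERS:
        try:
            gc = group_comparison(sub[param].to_numpy(dtype=float), sub["group"].to_numpy())
        except ValueError as exc:
            rows.append({"parameter": param, "source": source, "note": str(exc)})
            continue
        row = {"parameter": param, "source": source, **asdict(gc), "note": ""}
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of each necrosis parameter against the modified Kerboul
    angle, per segmentation source."""
    rows = []
    for param in KERBOUL_PARAMETERS:
        for source, sub in df.groupby("source", sort=True):
            v = sub[param].to_numpy(dtype=float)
            k = sub["kerboul_modified"].to_numpy(dtype=float)
            if len(v) < 3:
                rows.append({"parameter": param, "source": source, "note": "insufficient-n"})
                continue
            if np.std(v) == 0 or np.std(k) == 0:
                rows.append({"parameter": param, "source": source, "note": "constant-input"})
                continue
            r, p = sps.pearsonr(v, k)
            rows.append(
                {"parameter": param, "source": source, "n": len(v), "pearson_r": float(r), "p_value": float(p), "note": ""}
            )
    return pd.DataFrame(rows)


def build_report(
    df: pd.DataFrame,
    outdir: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the four report tables (CSV) plus a full-precision JSON.

    ``df`` is the tidy per-case frame described above; cases missing a
    source are reported in the JSON under ``excluded`` rather than
    silently dropped from paired tables (pairing intersects case ids).
    Byte-identical for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"

    outputs: dict[str, Path] = {}

    def _write(name: str, table: pd.DataFrame) -> None:
        path = outdir / name
        table.to_csv(path, index=False, float_format=fmt)
        outputs[name] = path

    _write("summary.csv", summary_table(df))

    sources = set(df["source"])
    paired_specs = [
        ("paired_3d_vs_2d.csv", "manual3d", "manual2d"),
        ("paired_2d_vs_auto.csv", "manual2d", "auto2d"),
    ]
    excluded: dict[str, list[str]] = {}
    for name, sa, sb in paired_specs:
        if sa in sources and sb in sources:
            _write(name, paired_table(df, sa, sb))
            ids_a = set(df.loc[df["source"] == sa, "case_id"])
            ids_b = set(df.loc[df["source"] == sb, "case_id"])
            missing = sorted(ids_a.symmetric_difference(ids_b))
            if missing:
                excluded[name] = missing

    group_frames = []
    for source in sorted(sources):
        sub = df[df["source"] == source]
        if sub["group"].nunique() < 2:
            excluded[f"group_comparison:{source}"] = ["single-group cohort; comparison skipped"]
            continue
        group_frames.append(group_table(df, source))
    if group_frames:
        _write("group_comparison.csv", pd.concat(group_frames, ignore_index=True))

    _write("kerboul_correlations.csv", correlation_table(df))

    report = {
        "metadata": dict(metadata or {}),
        "conventions": {
            "alpha": ALPHA,
            "sidedness": "two-sided",
            "iqr": "linear-interpolation quantiles, Q3 - Q1",
            "dice_empty_vs_empty": 1.0,
            "multiple_testing_correction": None,
            "mannwhitney_exact_max_n": EXACT_MWU_MAX_N,
        },
        "excluded": excluded,
        "tables": {
            name.removesuffix(".csv"): json.loads(
                pd.read_csv(path).to_json(orient="records")
            )
            for name, path in outputs.items()
        },
        "cases": json.loads(df.to_json(orient="records")),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    outputs["report.json"] = report_path
    return outputs
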