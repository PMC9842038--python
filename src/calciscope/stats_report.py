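"""Group-comparison statistics and study orchestration.

The measurement modules produce one scalar per image (correlation length,
normalized staining density, cell:ECM ratio, ...); this module compares
those scalars across condition groups with the tests standard in imaging
studies — Welch's t test for two groups, one-way ANOVA with Dunnett or
Tukey post hoc for several — and runs whole synthetic studies end to end
through :func:`run_study`.

Dunnett's many-to-one adjustment is computed from the multivariate-t
dependency structure of the comparison statistics (scipy); an independent
Monte-Carlo evaluation of the same max-|t| null is provided in
:func:`dunnett_montecarlo` so the adjustment can be cross-checked rather
than trusted as a table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupComparisonResult",
    "StudyReport",
    "welch_t",
    "one_way_anova",
    "two_way_anova",
    "dunnett_montecarlo",
    "run_study",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupComparisonResult:
    """One hypothesis test: statistic, p, and any post hoc adjustments."""

    test_name: str
    groups: dict[str, int]  # label -> n
    statistic: float
    p_value: float
    posthoc: Optional[list[tuple[tuple[str, str], float]]] = None
    alpha: float = 0.05
    effects: Optional[dict[str, tuple[float, float]]] = None  # two-way: name -> (F, p)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size < 2:
        raise ValidationError(f"sample {name!r} needs n >= 2, got n = {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"sample {name!r} contains non-finite values")
    return arr


def welch_t(a, b, labels: tuple[str, str] = ("a", "b"), alpha: float = 0.05) -> GroupComparisonResult:
    """Two-sided Welch (unequal-variance) t test."""
    a = _as_sample(a, labels[0])
    b = _as_sample(b, labels[1])
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate but well-defined when the means coincide
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparisonResult(
        test_name="welch_t",
        groups={labels[0]: a.size, labels[1]: b.size},
        statistic=t_stat,
        p_value=p,
        alpha=alpha,
    )


def dunnett_montecarlo(
    t_observed, n_groups: int, n_per_group: int, n_draws: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo adjusted p's for balanced many-to-one comparisons.

    Simulates the null distribution of max_i |t_i| where
    t_i = (xbar_i - xbar_0) / (s * sqrt(2/n)) across the k-1 treatment
    vs. control contrasts sharing the pooled error estimate, and returns
    P(max |T| >= |t_obs|) per observed statistic. Used as the independent
    reference for the multivariate-t computation.
    """
    k, n = int(n_groups), int(n_per_group)
    if k < 2 or n < 2:
        raise ValidationError("need >= 2 groups with n >= 2 each")
    df = k * (n - 1)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))  # scaled group means under H0
    s2 = rng.chisquare(df, n_draws) / df
    t_null = (z[:, 1:] - z[:, :1]) / np.sqrt(2.0 * s2[:, None])
    tmax = np.abs(t_null).max(axis=1)
    t_observed = np.atleast_1d(np.asarray(t_observed, dtype=np.float64))
    return np.array([(tmax >= abs(t)).mean() for t in t_observed])


def one_way_anova(
    groups: dict[str, "np.ndarray"],
    posthoc: str = "none",
    control: str | None = None,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """One-way ANOVA with optional Dunnett (vs. a control) or Tukey HSD.

    ``posthoc`` is one of ``"none"``, ``"dunnett"`` (requires
    ``control`` naming one group) or ``"tukey"``. Dunnett adjusted p's
    come from the multivariate-t distribution of the simultaneous
    contrasts.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    samples = {lab: _as_sample(v, lab) for lab, v in groups.items()}
    f_res = stats.f_oneway(*samples.values())
    f_stat, p = float(f_res.statistic), float(f_res.pvalue)
    if all(s.var(ddof=1) == 0 for s in samples.values()) and f_stat != f_stat:
        f_stat, p = 0.0, 1.0

    posthoc_rows: list[tuple[tuple[str, str], float]] | None = None
    if posthoc == "dunnett":
        if control is None or control not in samples:
            raise ValidationError(f"dunnett post hoc requires a control label among {list(samples)}")
        treat_labels = [lab for lab in samples if lab != control]
        res = stats.dunnett(*(samples[lab] for lab in treat_labels), control=samples[control])
        posthoc_rows = [
            ((lab, control), float(pv)) for lab, pv in zip(treat_labels, res.pvalue)
        ]
    elif posthoc == "tukey":
        labels = list(samples)
        res = stats.tukey_hsd(*samples.values())
        posthoc_rows = [
            ((labels[i], labels[j]), float(res.pvalue[i, j]))
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    elif posthoc != "none":
        raise ValidationError(f"unknown posthoc {posthoc!r}")

    return GroupComparisonResult(
        test_name="one_way_anova" + ("" if posthoc == "none" else f"+{posthoc}"),
        groups={lab: s.size for lab, s in samples.items()},
        statistic=f_stat,
        p_value=p,
        posthoc=posthoc_rows,
        alpha=alpha,
    )


def two_way_anova(
    values,
    factor_a,
    factor_b,
    posthoc: str = "none",
    control: str | None = None,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Balanced two-factor ANOVA with interaction.

    The standard two-factor sum-of-squares decomposition (which for a
    balanced full-factorial design is unambiguous); unbalanced designs
    are rejected rather than silently re-weighted. ``statistic`` and
    ``p_value`` report the interaction term; main effects are in
    ``effects``. Post hoc tests act on the cell means (labels
    ``"a:b"``).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=np.float64),
            "fa": np.asarray(factor_a, dtype=object),
            "fb": np.asarray(factor_b, dtype=object),
        }
    )
    cells = df.groupby(["fa", "fb"], sort=True).size()
    n_a, n_b = df["fa"].nunique(), df["fb"].nunique()
    if len(cells) != n_a * n_b:
        raise ValidationError("empty cells: a full factorial design is required")
    if cells.nunique() != 1:
        raise ValidationError("unbalanced design rejected; equalize cell sizes first")
    if cells.iloc[0] < 2:
        raise ValidationError("need n >= 2 per cell")

    model = ols("value ~ C(fa) + C(fb) + C(fa):C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {
        "factor_a": (float(table.loc["C(fa)", "F"]), float(table.loc["C(fa)", "PR(>F)"])),
        "factor_b": (float(table.loc["C(fb)", "F"]), float(table.loc["C(fb)", "PR(>F)"])),
        "interaction": (
            float(table.loc["C(fa):C(fb)", "F"]),
            float(table.loc["C(fa):C(fb)", "PR(>F)"]),
        ),
    }

    posthoc_rows = None
    if posthoc in ("dunnett", "tukey"):
        cell_groups = {
            f"{a}:{b}": grp["value"].to_numpy() for (a, b), grp in df.groupby(["fa", "fb"], sort=True)
        }
        posthoc_rows = one_way_anova(cell_groups, posthoc=posthoc, control=control, alpha=alpha).posthoc
    elif posthoc != "none":
        raise ValidationError(f"unknown posthoc {posthoc!r}")

    return GroupComparisonResult(
        test_name="two_way_anova" + ("" if posthoc == "none" else f"+{posthoc}"),
        groups={str(k): int(v) for k, v in cells.items()},
        statistic=effects["interaction"][0],
        p_value=effects["interaction"][1],
        posthoc=posthoc_rows,
        alpha=alpha,
        effects=effects,
    )


# ---------------------------------------------------------------------------
# study orchestration


@dataclass
class StudyReport:
    """All outputs of one study run: per-image rows, summaries, tests."""

    per_image_table: pd.DataFrame
    group_summaries: pd.DataFrame
    comparisons: list[GroupComparisonResult]
    config_echo: dict


def _image_seed(base_seed: int, group_index: int, image_index: int) -> int:
    return int((base_seed * 1_000_003 + group_index * 10_007 + image_index) % (2**31))


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _collect_group_images(group: dict, gidx: int, base_seed: int, calibration: float):
    """Yield (source_id, CalibratedImage or stack+truth) per image of a group."""
    from . import image_io, synthetic_data

    label = group["label"]
    if "preset" in group:
        spec0 = synthetic_data.preset(group["preset"], **group.get("overrides", {}))
        for i in range(int(group.get("n_images", 1))):
            seed = _image_seed(base_seed, gidx, i)
            from dataclasses import replace

            spec = replace(spec0, seed=seed)
            if isinstance(spec, synthetic_data.PunctaFieldSpec):
                img, gt = synthetic_data.gen_puncta_field(spec)
                yield f"{label}-{i:02d}", ("puncta", img, gt)
            else:
                stk, gt = synthetic_data.gen_if_scene(spec)
                yield f"{label}-{i:02d}", ("stack", stk, gt)
    elif "images" in group:
        kind = group.get("kind", "puncta")
        for i, p in enumerate(group["images"]):
            if kind == "stack":
                stk = image_io.read_stack(
                    p,
                    {int(k): v for k, v in group["channel_roles"].items()},
                    calibration,
                    group.get("z_step_um", 1.0),
                )
                yield stk.source_id, ("stack", stk, None)
            else:
                img = image_io.read_image(p, calibration)
                yield img.source_id, (kind, img, None)
    else:
        raise ValidationError(f"group {label!r} needs either 'preset' or 'images'")


def run_study(config) -> StudyReport:
    """Run the configured stages over all groups and compare the metrics.

    ``config`` is a dict or a YAML path with keys: ``seed``,
    ``calibration``, ``groups`` (label + preset/n_images or image
    paths), ``stages`` (subset of ``vk``, ``corrlength``,
    ``localization``), stage parameters (``threshold``, ``max_lag``,
    ``dilation_px``, ``min_area_px``), ``comparisons`` (metric, test,
    groups, optional posthoc/control) and optionally ``outdir``.
    Re-running an identical config reproduces every output byte for
    byte; nothing time- or host-dependent enters the report.
    """
    from . import autocorr, localization, vk_quant
    from .image_io import RGBImage

    cfg = _load_config(config)
    base_seed = int(cfg.get("seed", 0))
    calibration = float(cfg.get("calibration", 2.73))
    stages = list(cfg.get("stages", ["vk", "corrlength"]))
    threshold_policy = cfg.get("threshold", "auto")
    max_lag = cfg.get("max_lag", "auto")
    dilation_px = int(cfg.get("dilation_px", localization.DEFAULT_DILATION_PX))
    min_area_px = int(cfg.get("min_area_px", localization.DEFAULT_MIN_AREA_PX))

    # pass 1: materialize all inputs (the uniform threshold needs the pool)
    items: list[tuple[str, str, str, object, object]] = []  # label, sid, kind, obj, gt
    for gidx, group in enumerate(cfg["groups"]):
        for sid, (kind, obj, gt) in _collect_group_images(group, gidx, base_seed, calibration):
            items.append((group["label"], sid, kind, obj, gt))

    threshold_used: int | None = None
    if "vk" in stages or "corrlength" in stages:
        grays = []
        for _, _, kind, obj, _ in items:
            if kind == "puncta":
                grays.append(vk_quant.rgb_to_gray8(obj) if isinstance(obj, RGBImage) else obj)
        if grays:
            if threshold_policy == "auto":
                threshold_used = vk_quant.auto_threshold(grays)
            else:
                threshold_used = int(threshold_policy)
            logger.info("run_study: uniform threshold = %d", threshold_used)

    rows = []
    for label, sid, kind, obj, gt in items:
        row: dict = {"condition": label, "source_id": sid}
        if kind == "puncta":
            gray = vk_quant.rgb_to_gray8(obj) if isinstance(obj, RGBImage) else obj
            mask = vk_quant.binarize_dark(gray, threshold_used)
            if "vk" in stages:
                vk = vk_quant.integrated_density(mask, threshold_used=threshold_used, source_id=sid)
                row.update(
                    threshold_used=vk.threshold_used,
                    n_foreground_px=vk.n_foreground_px,
                    integrated_density=vk.integrated_density,
                    area_fraction=vk.area_fraction,
                    normalized_density=vk.normalized_density,
                )
            if "corrlength" in stages:
                ml = autocorr.default_max_lag(mask) if max_lag == "auto" else int(max_lag)
                try:
                    cl = autocorr.correlation_length_from_mask(mask, ml, source_id=sid)
                except ValidationError as exc:
                    # constant mask (e.g. a blank control): report the gap, keep the row
                    row.update(
                        correlation_length_px=np.nan,
                        correlation_length_um=np.nan,
                        crossing_lag_px=np.nan,
                        crossed_zero=False,
                        low_support=True,
                        note=str(exc),
                    )
                else:
                    row.update(
                        correlation_length_px=cl.correlation_length_px,
                        correlation_length_um=cl.correlation_length_um,
                        crossing_lag_px=cl.integration_upper_lag_px,
                        crossed_zero=cl.crossed_zero,
                        low_support=cl.low_support,
                    )
        elif kind == "stack" and "localization" in stages:
            loc = localization.localize(obj, dilation_px=dilation_px, min_area_px=min_area_px)
            sig = localization.median_projection(obj, "signal")
            row.update(
                n_nuclei=loc.n_nuclei,
                dilation_px=loc.dilation_px,
                cell_mean=loc.cell_mean,
                ecm_mean=loc.ecm_mean,
                ratio=loc.ratio,
                cellular_fraction=loc.cellular_fraction,
                mean_fluorescence=localization.mean_fluorescence(sig),
            )
        rows.append(row)

    per_image = pd.DataFrame(rows)
    metric_cols = [c for c in per_image.columns if per_image[c].dtype.kind == "f"]
    summaries = (
        per_image.groupby("condition", sort=False)[metric_cols].agg(["mean", "std"])
        if metric_cols
        else pd.DataFrame()
    )

    comparisons: list[GroupComparisonResult] = []
    for comp in cfg.get("comparisons", []):
        metric = comp["metric"]
        labels = comp.get("groups") or list(per_image["condition"].unique())
        data = {}
        for lab in labels:
            vals = per_image.loc[per_image["condition"] == lab, metric].to_numpy()
            data[lab] = vals[np.isfinite(vals)]  # gap rows are excluded per group
        test = comp.get("test", "welch")
        try:
            if test == "welch":
                if len(labels) != 2:
                    raise ValidationError("welch comparison needs exactly two groups")
                res = welch_t(data[labels[0]], data[labels[1]], labels=(labels[0], labels[1]))
            elif test == "anova":
                res = one_way_anova(
                    data, posthoc=comp.get("posthoc", "none"), control=comp.get("control")
                )
            else:
                raise ValidationError(f"unknown test {test!r}")
        except ValidationError as exc:
            # e.g. a group lost too many images to gaps: report, don't abort
            logger.warning("comparison on %r not computable: %s", metric, exc)
            res = GroupComparisonResult(
                test_name=f"{test}(failed: {exc})",
                groups={lab: int(v.size) for lab, v in data.items()},
                statistic=np.nan,
                p_value=np.nan,
            )
        res.test_name = f"{metric}:{res.test_name}"
        comparisons.append(res)

    config_echo = dict(cfg)
    config_echo.pop("outdir", None)  # output location is not an analysis parameter
    config_echo["resolved"] = {
        "threshold_used": threshold_used,
        "dilation_px": dilation_px,
        "min_area_px": min_area_px,
        "calibration": calibration,
        "seed": base_seed,
        "package": "calciscope",
    }

    report = StudyReport(per_image, summaries, comparisons, config_echo)
    outdir = cfg.get("outdir")
    if outdir:
        _write_report(report, Path(outdir))
    return report


def _comparison_dict(c: GroupComparisonResult) -> dict:
    return {
        "test_name": c.test_name,
        "groups": c.groups,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "posthoc": [[list(pair), p] for pair, p in c.posthoc] if c.posthoc else None,
        "alpha": c.alpha,
        "effects": c.effects,
    }


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_image_table.to_csv(outdir / "per_image.csv", index=False)
    comp_rows = []
    for c in report.comparisons:
        comp_rows.append(
            {
                "test_name": c.test_name,
                "groups": ";".join(f"{k}={v}" for k, v in c.groups.items()),
                "statistic": c.statistic,
                "p_value": c.p_value,
                "significant": c.p_value < c.alpha,
            }
        )
    pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)
    payload = {
        "config": report.config_echo,
        "comparisons": [_comparison_dict(c) for c in report.comparisons],
        "group_summaries": json.loads(report.group_summaries.to_json(orient="index"))
        if len(report.group_summaries)
        else {},
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")
    lines = [
        "calciscope study log",
        f"images: {len(report.per_image_table)}",
        f"threshold_used: {report.config_echo['resolved']['threshold_used']}",
        f"seed: {report.config_echo['resolved']['seed']}",
    ]
    lines += [f"{r['test_name']}: p = {r['p_value']:.6g}" for r in comp_rows]
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
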