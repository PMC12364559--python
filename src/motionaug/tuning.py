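"""Tuning-grid expansion, per-method selection and reporting.

Detector training is out of process: this module enumerates candidate
augmentation configurations, each of which :func:`~motionaug.augment.
augment_dataset` turns into a dataset copy for an external detector to
train on; the resulting validation metrics come back as
:class:`TuningRecord` rows and :func:`select_best` picks a winner per
method. Selection reads validation-split records only — the test split
is reserved for the final comparison — and keeps an audit of which
splits it consulted so that guarantee is checkable.

The default grids reflect the parameter ranges that matter in practice:
frame offsets ``dt`` of a frame or two for video (seconds-long gaps for
burst imagery), signal scalings ``upsilon`` of 1 (raw differences) or
15 (strong amplification for subtle motion), and all three channel
modes. Two-stage tuning — motion parameters first with a fixed mode,
then the mode with frozen parameters — is the default; a single full
grid is available via ``expand_grid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from itertools import product

import pandas as pd

__all__ = ["AugmentationConfig", "TuningRecord", "expand_grid", "select_best", "SelectionResult", "report"]

_MODE_ORDER = {"all": 0, "red": 1, "pca": 2}

# which fields are meaningful for each motion method
_FIELDS_BY_METHOD = {
    "raw": set(),
    "fd": {"approach", "dt", "upsilon", "mode"},
    "bs_fd": {"n_b", "dt_b", "upsilon", "mode"},
    "bs_knn": {"mode"},
    "flow": {"dt", "estimator", "mode"},
}


@dataclass(frozen=True)
class AugmentationConfig:
    """One point of the tuning grid.

    Fields that a method does not use must stay ``None`` (validated):
    ``raw`` takes nothing, frame differencing takes (approach, dt,
    upsilon), background subtraction via differencing takes (n_b, dt_b,
    upsilon), the KNN mask takes only a mode, and optical flow takes
    (dt, estimator). ``seed`` feeds every stochastic step downstream
    (PCA sampling) and is not part of the grid identity checks.
    """

    method: str
    approach: str | None = None  # fd_a | fd_d (fd only)
    dt: int | None = None
    upsilon: float | None = None
    n_b: int | None = None
    dt_b: int | None = None
    mode: str | None = None  # all | red | pca
    estimator: str | None = None  # flow only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _FIELDS_BY_METHOD:
            raise ValueError(f"unknown method {self.method!r}")
        allowed = _FIELDS_BY_METHOD[self.method]
        for f in ("approach", "dt", "upsilon", "n_b", "dt_b", "mode", "estimator"):
            value = getattr(self, f)
            if value is not None and f not in allowed:
                raise ValueError(f"field {f!r} is not applicable to method {self.method!r}")
        if self.method != "raw" and self.mode not in _MODE_ORDER:
            raise ValueError(f"method {self.method!r} needs mode in {{all, red, pca}}, got {self.mode!r}")
        if self.method == "fd" and self.approach not in {"fd_a", "fd_d"}:
            raise ValueError(f"fd needs approach fd_a or fd_d, got {self.approach!r}")
        if self.dt is not None and self.dt < 1:
            raise ValueError("dt must be >= 1")
        if self.upsilon is not None and self.upsilon < 0:
            raise ValueError("upsilon must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TuningRecord:
    """External-detector metrics for one config on one split."""

    config: AugmentationConfig
    split: str
    metrics: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.split not in {"val", "test"}:
            raise ValueError(f"split must be val or test, got {self.split!r}")
        for name, v in self.metrics.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"metric {name}={v} outside [0, 1]")


_DEFAULT_GRID = {
    "methods": ["raw", "fd", "bs_fd", "bs_knn", "flow"],
    "approach": ["fd_a", "fd_d"],
    "dt": [1, 4],
    "upsilon": [1.0, 15.0],
    "n_b": [10],
    "dt_b": [1],
    "mode": ["all", "red", "pca"],
    "estimator": ["block_match"],
}


def expand_grid(grid: dict | None = None, seed: int = 0) -> list[AugmentationConfig]:
    """Cartesian product of grid values, restricted per method.

    Fields a method does not use are held at ``None`` rather than
    multiplied out, so ``raw`` contributes exactly one config.
    Deterministic order: methods as listed, then field values in listed
    order. Raises on an empty grid.
    """
    g = dict(_DEFAULT_GRID)
    if grid:
        g.update(grid)
    if not g.get("methods"):
        raise ValueError("grid lists no methods")
    axes_by_method = {
        "raw": [],
        "fd": ["approach", "dt", "upsilon", "mode"],
        "bs_fd": ["n_b", "dt_b", "upsilon", "mode"],
        "bs_knn": ["mode"],
        "flow": ["dt", "estimator", "mode"],
    }
    configs: list[AugmentationConfig] = []
    for method in g["methods"]:
        axes = axes_by_method[method]
        value_lists = [g[a] for a in axes]
        if any(not v for v in value_lists):
            raise ValueError(f"grid has an empty axis for method {method!r}")
        for combo in product(*value_lists) if axes else [()]:
            kwargs = dict(zip(axes, combo))
            configs.append(AugmentationConfig(method=method, seed=seed, **kwargs))
    return configs


@dataclass
class SelectionResult:
    """Winners per method plus an audit of what selection looked at."""

    best: dict[str, AugmentationConfig]
    audit: dict


def _tie_key(metric_value: float, c: AugmentationConfig) -> tuple:
    # maximise metric; break ties by smaller dt, smaller upsilon, mode order
    return (
        -metric_value,
        c.dt if c.dt is not None else 0,
        c.upsilon if c.upsilon is not None else 0.0,
        _MODE_ORDER.get(c.mode, -1),
    )


def select_best(
    records: list[TuningRecord],
    criterion: str = "map50",
    two_stage: bool = False,
    stage_one_mode: str = "all",
) -> SelectionResult:
    """Pick the best config per method by validation-split metric.

    Only ``split='val'`` records are consulted; the audit in the result
    lists the splits actually read so the no-test-leakage guarantee can
    be asserted. Ties break towards smaller ``dt``, then smaller
    ``upsilon``, then mode order all < red < pca.

    With ``two_stage=True`` the motion parameters are chosen first
    among records whose mode equals ``stage_one_mode``, then the mode is
    chosen among records sharing those frozen parameters — mirroring a
    workflow where motion tuning and augmentation-mode tuning are
    separate passes.
    """
    val = [r for r in records if r.split == "val"]
    audit = {
        "consulted_splits": sorted({r.split for r in val}),
        "n_records_seen": len(val),
        "criterion": criterion,
        "two_stage": two_stage,
    }
    if not val:
        raise ValueError("no validation-split records to select from")
    missing = [r.config.method for r in val if criterion not in r.metrics]
    if missing:
        raise ValueError(f"records for methods {sorted(set(missing))} lack metric {criterion!r}")

    by_method: dict[str, list[TuningRecord]] = {}
    for r in val:
        by_method.setdefault(r.config.method, []).append(r)

    best: dict[str, AugmentationConfig] = {}
    for method, recs in by_method.items():
        if two_stage and method != "raw":
            stage1 = [r for r in recs if r.config.mode == stage_one_mode] or recs
            winner1 = min(stage1, key=lambda r: _tie_key(r.metrics[criterion], r.config))
            frozen = winner1.config
            same_params = [
                r
                for r in recs
                if (r.config.approach, r.config.dt, r.config.upsilon, r.config.n_b, r.config.dt_b, r.config.estimator)
                == (frozen.approach, frozen.dt, frozen.upsilon, frozen.n_b, frozen.dt_b, frozen.estimator)
            ]
            best[method] = min(same_params, key=lambda r: _tie_key(r.metrics[criterion], r.config)).config
        else:
            best[method] = min(recs, key=lambda r: _tie_key(r.metrics[criterion], r.config)).config
    return SelectionResult(best=best, audit=audit)


def report(records: list[TuningRecord], split: str = "test") -> pd.DataFrame:
    """Per-method x metric comparison table with best-per-column flags.

    Returns a DataFrame indexed by method; metric columns hold the
    values and a parallel ``<metric>_best`` boolean column flags the
    column maximum. Deterministic for fixed input.
    """
    rows = [r for r in records if r.split == split]
    if not rows:
        raise ValueError(f"no records for split {split!r}")
    metric_names = sorted({m for r in rows for m in r.metrics})
    data = {}
    for r in rows:
        data[r.config.method] = {m: r.metrics.get(m) for m in metric_names}
    df = pd.DataFrame.from_dict(data, orient="index")[metric_names].sort_index()
    for m in metric_names:
        df[f"{m}_best"] = df[m] == df[m].max()
    return df


def report_markdown(df: pd.DataFrame) -> str:
    """Render a :func:`report` table as Markdown, bolding column maxima."""
    metrics = [c for c in df.columns if not c.endswith("_best")]
    lines = ["| method | " + " | ".join(metrics) + " |", "|" + "---|" * (len(metrics) + 1)]
    for method, row in df.iterrows():
        cells = []
        for m in metrics:
            v = row[m]
            cell = f"{v:.3f}" if pd.notna(v) else "NA"
            if row.get(f"{m}_best", False):
                cell = f"**{cell}**"
            cells.append(cell)
        lines.append(f"| {method} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
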