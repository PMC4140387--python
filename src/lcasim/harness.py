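"""Monte-Carlo execution of design cells with refill and exclusion policies.

Each cell runs an initial batch of ``target_reps`` replications. If fewer
than half of the initial batch are usable, the cell is excluded outright;
otherwise batches sized three times the current shortfall are re-simulated
(with fresh, deterministically derived seeds) until the cell holds
``target_reps`` usable replications, keeping the design balanced. Seeds are
derived from (root seed, cell identity, replication index), so results do
not depend on cell ordering or the degree of parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datagen import generate_dataset, zero_variance_check
from .design import DesignCell, build_population_spec
from .diagnostics import (
    DEFAULT_ACCURACY_FLOOR,
    STATUSES,
    ReplicationRecord,
    classify_replication,
)
from .estimator import ParameterSet, fit
from .metrics import boundary_prevalence, crp_bias, structural_bias

#: maximum refill rounds per cell before giving up (distinct from the 50% rule)
MAX_REFILL_ROUNDS = 10


@dataclass
class CellSummary:
    """Per-condition aggregates over a replication set."""

    cell: DesignCell
    n_initial: int
    status_counts: dict[str, int]           # over the initial batch only
    n_usable: int                           # usable replications accumulated overall
    included: bool
    exclusion_reason: str | None
    refills_used: int
    metrics: dict = field(default_factory=dict)


def replication_seed(root_seed: int, cell: DesignCell, rep_index: int) -> int:
    """Deterministic per-replication seed from the root seed and cell identity."""
    ss = np.random.SeedSequence([int(root_seed), cell.seed_key(), int(rep_index)])
    return int(ss.generate_state(1, np.uint32)[0])


def run_replication(
    cell: DesignCell,
    rep_index: int,
    root_seed: int,
    accuracy_floor: float = DEFAULT_ACCURACY_FLOOR,
    max_iter: int = 500,
    tol: float = 1e-7,
    keep_fit: bool = True,
) -> ReplicationRecord:
    """Generate, fit (from true-parameter starts), classify, and score one replication."""
    spec = build_population_spec(cell)
    seed = replication_seed(root_seed, cell, rep_index)
    d = generate_dataset(spec, cell.sample_size, seed)

    _, any_constant = zero_variance_check(d)
    fit_res = None
    if not any_constant:
        fit_res = fit(d, ParameterSet.from_spec(spec), max_iter=max_iter, tol=tol)
    status, perm = classify_replication(fit_res, d, accuracy_floor)

    bias = None
    if status == "ok":
        hb, lb = crp_bias(fit_res.estimate.crp, spec.crp)
        sb = structural_bias(fit_res.estimate, spec)
        bias = {
            "crp_high": hb,
            "crp_low": lb,
            "class_proportion": sb["class_proportion"],
            "slope": sb["slope"],
        }
    return ReplicationRecord(
        cell=cell,
        replication_index=rep_index,
        seed=seed,
        status=status,
        permutation=perm,
        loglik=fit_res.loglik if fit_res is not None else np.nan,
        n_iterations=fit_res.n_iterations if fit_res is not None else 0,
        boundary_count=fit_res.boundary_count if fit_res is not None else 0,
        bias=bias,
        fit=fit_res if keep_fit else None,
    )


def _summarize(cell, records, initial, usable, included, reason, refills, target_reps):
    counts = {s: 0 for s in STATUSES}
    for r in initial:
        counts[r.status] += 1
    metrics: dict = {
        "prop_nonconverged": counts["nonconverged"] / len(initial),
        "prop_incorrigible": counts["incorrigible"] / len(initial),
        "prop_label_switched": counts["label_switched"] / len(initial),
        "prop_zero_variance": counts["zero_variance"] / len(initial),
    }
    if included:
        contrib = usable[:target_reps]
        metrics["boundary_prevalence"] = boundary_prevalence(contrib)
        metrics["crp_high_bias"] = float(np.mean([r.bias["crp_high"] for r in contrib]))
        metrics["crp_low_bias"] = float(np.mean([r.bias["crp_low"] for r in contrib]))
        cp = np.array([r.bias["class_proportion"] for r in contrib])
        for k in range(cp.shape[1]):
            metrics[f"class_{k + 1}_bias"] = float(cp[:, k].mean())
        slopes = [r.bias["slope"] for r in contrib if r.bias["slope"] is not None]
        metrics["slope_bias"] = float(np.mean(slopes)) if slopes else np.nan
    return CellSummary(
        cell=cell,
        n_initial=len(initial),
        status_counts=counts,
        n_usable=len(usable),
        included=included,
        exclusion_reason=reason,
        refills_used=refills,
        metrics=metrics,
    )


def run_cell(
    cell: DesignCell,
    target_reps: int = 1000,
    root_seed: int = 0,
    accuracy_floor: float = DEFAULT_ACCURACY_FLOOR,
    max_iter: int = 500,
    tol: float = 1e-7,
    keep_fits: bool = False,
) -> tuple[CellSummary, list[ReplicationRecord]]:
    """Run one design cell under the replication, refill, and exclusion policies.

    The 50% usability rule is evaluated on the initial batch only. Refill
    batches are sized at three times the current shortfall of usable
    replications, up to ``MAX_REFILL_ROUNDS`` rounds.
    """
    if target_reps < 1:
        raise ValueError("target_reps must be >= 1")
    kw = dict(root_seed=root_seed, accuracy_floor=accuracy_floor,
              max_iter=max_iter, tol=tol, keep_fit=keep_fits)

    initial = [run_replication(cell, i, **kw) for i in range(target_reps)]
    records = list(initial)
    usable = [r for r in initial if r.status == "ok"]

    if len(usable) / target_reps < 0.5:
        return _summarize(cell, records, initial, usable, False, "unusable_majority", 0,
                          target_reps), records

    next_index = target_reps
    refills = 0
    while len(usable) < target_reps and refills < MAX_REFILL_ROUNDS:
        shortfall = target_reps - len(usable)
        batch = [run_replication(cell, next_index + i, **kw) for i in range(3 * shortfall)]
        next_index += len(batch)
        refills += 1
        records.extend(batch)
        usable.extend(r for r in batch if r.status == "ok")

    if len(usable) < target_reps:
        return _summarize(cell, records, initial, usable, False, "refill_exhausted",
                          refills, target_reps), records
    return _summarize(cell, records, initial, usable, True, None, refills, target_reps), records


def run_grid(
    cells: list[DesignCell],
    target_reps: int = 1000,
    root_seed: int = 0,
    n_jobs: int = 1,
    **cell_kwargs,
) -> tuple[list[CellSummary], list[ReplicationRecord]]:
    """Run a list of cells independently; results depend only on the root seed.

    A cell raising an unexpected error is recorded as an excluded summary
    with the error message; it never aborts the grid.
    """

    def _one(cell: DesignCell):
        try:
            return run_cell(cell, target_reps=target_reps, root_seed=root_seed, **cell_kwargs)
        except Exception as exc:  # noqa: BLE001 - contract: record, don't abort
            summary = CellSummary(
                cell=cell, n_initial=0, status_counts={s: 0 for s in STATUSES},
                n_usable=0, included=False, exclusion_reason=f"error: {exc}", refills_used=0,
            )
            return summary, []

    if n_jobs == 1:
        results = [_one(c) for c in cells]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(_one)(c) for c in cells)
    summaries = [s for s, _ in results]
    records = [r for _, recs in results for r in recs]
    return summaries, records


def _cell_fields(cell: DesignCell) -> dict:
    return {
        "n_classes": cell.n_classes,
        "sample_size": cell.sample_size,
        "n_indicators": cell.n_indicators,
        "quality": cell.quality,
        "covariate": cell.covariate,
    }


def records_to_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    """Replication log: one row per replication, suitable for CSV export."""
    rows = []
    for r in records:
        row = _cell_fields(r.cell) | {
            "replication_index": r.replication_index,
            "seed": r.seed,
            "status": r.status,
            "permutation": "-".join(str(p + 1) for p in r.permutation),
            "loglik": r.loglik,
            "n_iterations": r.n_iterations,
            "boundary_count": r.boundary_count,
        }
        if r.bias is not None:
            row["crp_high_bias"] = r.bias["crp_high"]
            row["crp_low_bias"] = r.bias["crp_low"]
            for k, b in enumerate(r.bias["class_proportion"]):
                row[f"class_{k + 1}_bias"] = b
            row["slope_bias"] = r.bias["slope"]
        rows.append(row)
    df = pd.DataFrame(rows)
    # canonical column order regardless of which cell type appears first
    lead = ["n_classes", "sample_size", "n_indicators", "quality", "covariate",
            "replication_index", "seed", "status", "permutation", "loglik",
            "n_iterations", "boundary_count", "crp_high_bias", "crp_low_bias"]
    cols = [c for c in lead if c in df.columns]
    cols += sorted(c for c in df.columns if c.startswith("class_") and c.endswith("_bias"))
    if "slope_bias" in df.columns:
        cols.append("slope_bias")
    return df.reindex(columns=cols)


def summaries_to_frame(summaries: list[CellSummary]) -> pd.DataFrame:
    """Per-cell summary table: status counts, inclusion, and outcome metrics."""
    rows = []
    for s in summaries:
        row = _cell_fields(s.cell) | {
            "n_initial": s.n_initial,
            "n_usable": s.n_usable,
            "included": s.included,
            "exclusion_reason": s.exclusion_reason,
            "refills_used": s.refills_used,
        }
        row |= {f"n_{k}": v for k, v in s.status_counts.items()}
        row |= s.metrics
        rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["n_classes", "sample_size", "n_indicators", "quality", "covariate",
            "n_initial", "n_usable", "included", "exclusion_reason", "refills_used",
            "n_ok", "n_nonconverged", "n_label_switched", "n_incorrigible",
            "n_zero_variance", "prop_nonconverged", "prop_incorrigible",
            "prop_label_switched", "prop_zero_variance", "boundary_prevalence",
            "crp_high_bias", "crp_low_bias"]
    cols = [c for c in lead if c in df.columns]
    cols += sorted(c for c in df.columns if c.startswith("class_") and c.endswith("_bias"))
    if "slope_bias" in df.columns:
        cols.append("slope_bias")
    return df.reindex(columns=cols)
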