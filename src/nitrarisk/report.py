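"""Combined analysis report: per-sample results, group summaries, run log.

The summary table mirrors the deterministic-vs-probabilistic layout of a
risk-assessment report: one row per exposure group and approach, with
mean, SD and P90 of the hazard quotient side by side.
"""

from __future__ import annotations

import platform
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

import nitrarisk

from .exposure import RiskResult, ValidationError, summarize
from .montecarlo import MCResult

__all__ = ["write_report"]


def _per_sample_frame(results: Sequence[RiskResult], threshold: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.sample_id for r in results],
            "group": [r.group_name for r in results],
            "edi": [r.edi for r in results],
            "hq": [r.hq for r in results],
            "exceeds": [r.hq > threshold for r in results],
        }
    )


def _summary_frame(
    results: Sequence[RiskResult], mc_results: Mapping[str, MCResult] | None
) -> pd.DataFrame:
    rows = []
    groups = list(dict.fromkeys(r.group_name for r in results))
    for g in groups:
        det = summarize(results, by=g)
        hq = np.array([r.hq for r in results if r.group_name == g])
        rows.append(
            {
                "group": g,
                "approach": "deterministic",
                "mean": det.hq["mean"],
                "sd": det.hq["sd"],
                "p90": float(np.quantile(hq, 0.90)),
                "p_exceedance": float(np.mean(hq > 1.0)),
            }
        )
        mc = (mc_results or {}).get(g)
        rows.append(
            {
                "group": g,
                "approach": "probabilistic",
                "mean": mc.mean if mc else "",
                "sd": mc.sd if mc else "",
                "p90": mc.percentile_table.get(0.90, "") if mc else "",
                "p_exceedance": mc.prob_exceedance if mc else "",
            }
        )
    return pd.DataFrame(rows)


def write_report(
    results: Sequence[RiskResult],
    out_dir: str | Path,
    mc_results: Mapping[str, MCResult] | None = None,
    raster_paths: Iterable[str | Path] = (),
    run_params: Mapping[str, object] | None = None,
    threshold: float = 1.0,
) -> dict[str, Path]:
    """Write the report files into ``out_dir``; returns their paths.

    Produces ``per_sample.csv`` (id, group, EDI, HQ, exceedance flag),
    ``summary.csv`` (per group: deterministic and probabilistic mean, SD,
    P90, exceedance probability; probabilistic cells empty when no MC
    result was supplied) and ``run_log.txt`` recording the package
    version and every parameter needed to re-execute identically.
    """
    results = list(results)
    if not results:
        raise ValidationError("no deterministic results to report")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths = {
        "per_sample": out_dir / "per_sample.csv",
        "summary": out_dir / "summary.csv",
        "run_log": out_dir / "run_log.txt",
    }
    _per_sample_frame(results, threshold).to_csv(
        paths["per_sample"], index=False, lineterminator="\n", float_format="%.6f"
    )
    _summary_frame(results, mc_results).to_csv(
        paths["summary"], index=False, lineterminator="\n", float_format="%.6f"
    )

    log = [
        f"nitrarisk {nitrarisk.__version__}",
        f"python {platform.python_version()}",
        f"exceedance threshold: {threshold}",
    ]
    for g, mc in (mc_results or {}).items():
        log.append(
            f"monte carlo [{g}]: n_iterations={mc.n_iterations} "
            f"rejected_draws={mc.n_rejected}"
        )
    for k, v in (run_params or {}).items():
        log.append(f"{k}: {v}")
    for rp in raster_paths:
        log.append(f"raster: {rp}")
    paths["run_log"].write_text("\n".join(log) + "\n", encoding="utf-8", newline="\n")
    return paths
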