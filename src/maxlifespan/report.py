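"""One-shot reproduction of the study's printed arithmetic, plus run configuration.

:func:`reproduce_reference` recomputes every headline number from the
published summary inputs (recorded in :mod:`maxlifespan.reference`) and
compares each against its printed value at printed precision:

* six worked-arithmetic rows — MLS1C, MLS^exp, MLSC, extension %, survival
  fold, chimerism % — are pure arithmetic on printed inputs and must match
  exactly; any mismatch is a defect.
* the model-tail row (MLS2C) re-evaluates the tail integral at the printed,
  *rounded* Gompertz parameters.  The published 17.2 was evidently computed
  from the authors' unrounded fit (the integral is sensitive at the 0.1-month
  level to rounding mu1 to one decimal), so this row is compared loosely and
  flagged ``informational``; it does not fail a reproduction run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import reference as ref
from .chimerism import chimerism_corrected
from .mls import (
    MLSEstimate,
    combine_weighted,
    extension_percent,
    mls_direct,
    mls_model_tail,
    student_ci,
    survival_fold,
)

__all__ = ["RunConfig", "reproduce_reference", "format_report", "report_json"]


@dataclass(frozen=True)
class RunConfig:
    """Shared knobs for the command-line entry points."""

    fraction: float = 0.1
    t_intervention: float = ref.T_INTERVENTION_MONTHS
    normalization: str = "proper"
    out: str | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ValueError("fraction must lie in (0, 0.5]")


def _row(name, computed, printed, decimals, comparison="exact"):
    match = round(computed, decimals) == round(printed, decimals)
    return {
        "quantity": name,
        "computed": computed,
        "printed": printed,
        "decimals": decimals,
        "match": bool(match),
        "comparison": comparison,
    }


def reproduce_reference(fraction: float = 0.1) -> dict:
    """Recompute every headline statistic from the published summary inputs.

    With ``fraction`` other than 0.1 the quantities are still computed but
    no printed comparison is defined (the published tails are top-decile).
    """
    compare = fraction == 0.1

    mls2c_model = mls_model_tail(ref.FITTED_PARAMS, fraction=fraction)
    if compare:
        mls1c = mls_direct(ref.CONTROL_TAIL_AGES, n_cohort=ref.CONTROL_N, fraction=fraction)
        mls_exp = mls_direct(
            ref.EXPERIMENTAL_TAIL_AGES, n_cohort=ref.EXPERIMENTAL_N_ANALYZED, fraction=fraction
        )

    # the weighted combination and downstream ratios use the printed inputs,
    # exactly as the published arithmetic does
    mlsc = combine_weighted(
        MLSEstimate(*ref.PRINTED["mls1c"], n_tail=2, method="direct", delta_source="printed"),
        MLSEstimate(*ref.PRINTED["mls2c"], n_tail=0, method="model_tail", delta_source="printed"),
    ).with_delta(ref.PRINTED["mlsc"][1], source="printed")
    ext = extension_percent(ref.PRINTED["mls_exp"][0], ref.PRINTED["mlsc"][0])
    fold = survival_fold(
        ref.PRINTED["mls_exp"][0], ref.PRINTED["mlsc"][0], ref.T_INTERVENTION_MONTHS
    )
    chim = chimerism_corrected(ref.OBSERVED_GFP_FRACTION, ref.DONOR_POSITIVE_FRACTION) * 100

    report = {
        "fraction": fraction,
        "printed_comparison": compare,
        "rows": [],
        "computed_student_ci": {
            "control_tail": student_ci(ref.CONTROL_TAIL_AGES),
            "experimental_tail": student_ci(ref.EXPERIMENTAL_TAIL_AGES),
        },
    }
    if compare:
        d = ref.PRINTED_DECIMALS
        report["rows"] = [
            _row("mls1c", mls1c.value, ref.PRINTED["mls1c"][0], d["mls1c"]),
            _row("mls_exp", mls_exp.value, ref.PRINTED["mls_exp"][0], d["mls_exp"]),
            _row("mlsc", mlsc.value, ref.PRINTED["mlsc"][0], d["mlsc"]),
            _row("extension_percent", ext, ref.PRINTED["extension_percent"][0], d["extension_percent"]),
            _row("survival_fold", fold, ref.PRINTED["survival_fold"][0], d["survival_fold"]),
            _row("chimerism_percent", chim, ref.PRINTED_CHIMERISM_PERCENT, d["chimerism_percent"]),
            _row(
                "mls2c_model_tail",
                mls2c_model.value,
                ref.PRINTED["mls2c"][0],
                d["mls2c"],
                comparison="informational",
            ),
        ]
        report["ok"] = all(r["match"] for r in report["rows"] if r["comparison"] == "exact")
    else:
        # the published tails are top-decile only, so direct estimates are
        # undefined at other fractions; report the model tail alone
        report["rows"] = [
            {"quantity": "mls2c_model_tail", "computed": mls2c_model.value},
        ]
        report["ok"] = True
    return report


def format_report(report: dict) -> str:
    """Human-readable table, one decimal as published; full precision in JSON."""
    lines = [f"{'quantity':<20}{'computed':>10}{'printed':>10}  status"]
    for r in report["rows"]:
        dec = r.get("decimals", 1)
        computed = f"{r['computed']:.{dec}f}"
        if "printed" in r:
            status = "ok" if r["match"] else (
                "note" if r["comparison"] == "informational" else "MISMATCH"
            )
            lines.append(
                f"{r['quantity']:<20}{computed:>10}{r['printed']:>10.{dec}f}  {status}"
            )
        else:
            lines.append(f"{r['quantity']:<20}{computed:>10}{'-':>10}")
    return "\n".join(lines)


def report_json(report: dict, path: str | Path | None = None) -> str:
    payload = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload
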