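"""Probe- and sample-level quality control from detection p-values.

A probe x sample detection p-value (e.g. pOOBAH-style) matrix drives two
filters:

* probe filter — a probe is excluded when its detection p exceeds
  ``fail_alpha`` in *more than* ``max_fail_fraction`` of samples (strict
  inequalities on both comparisons);
* sample filter — evaluated on the probes that survived the probe filter,
  a sample is removed when *less than* ``min_pass_fraction`` of probes
  pass (detection p strictly below ``pass_alpha``).

Probe QC runs first, then sample QC on the retained probes; applying the
pair again to the surviving submatrix changes nothing (single pass, no
iteration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_FAIL_ALPHA = 0.05
PROBE_MAX_FAIL_FRACTION = 0.10
SAMPLE_PASS_ALPHA = 0.05
SAMPLE_MIN_PASS_FRACTION = 0.96


class QcError(ValueError):
    """Structural problem in QC inputs (empty matrix, id mismatch)."""


@dataclass
class QcReport:
    """Outcome of probe- and sample-level detection QC.

    ``excluded_probes`` maps probe id -> reason; ``excluded_samples`` maps
    sample id -> fraction of probes passing. Retained and excluded ids
    partition the input ids.
    """

    retained_probes: list[str]
    excluded_probes: dict[str, str]
    retained_samples: list[str]
    excluded_samples: dict[str, float]
    thresholds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"probes retained {len(self.retained_probes)} / excluded "
            f"{len(self.excluded_probes)}; samples retained "
            f"{len(self.retained_samples)} / excluded {len(self.excluded_samples)}"
        )


def _check_matrix(detp: pd.DataFrame) -> None:
    if detp.shape[0] == 0 or detp.shape[1] == 0:
        raise QcError("detection p-value matrix is empty")


def filter_probes(
    detp: pd.DataFrame,
    fail_alpha: float = PROBE_FAIL_ALPHA,
    max_fail_fraction: float = PROBE_MAX_FAIL_FRACTION,
) -> QcReport:
    """Exclude probes failing detection in too many samples.

    A probe fails in a sample when detp > fail_alpha; it is excluded when
    the failing fraction strictly exceeds ``max_fail_fraction``.
    """
    _check_matrix(detp)
    n_samples = detp.shape[1]
    fail_frac = (detp.to_numpy() > fail_alpha).sum(axis=1) / n_samples
    bad = fail_frac > max_fail_fraction
    retained = detp.index[~bad].tolist()
    excluded = {
        pid: f"detection p > {fail_alpha} in {frac:.1%} of samples"
        for pid, frac in zip(detp.index[bad], fail_frac[bad])
    }
    return QcReport(
        retained_probes=retained,
        excluded_probes=excluded,
        retained_samples=detp.columns.tolist(),
        excluded_samples={},
        thresholds={"fail_alpha": fail_alpha, "max_fail_fraction": max_fail_fraction},
    )


def filter_samples(
    detp: pd.DataFrame,
    pass_alpha: float = SAMPLE_PASS_ALPHA,
    min_pass_fraction: float = SAMPLE_MIN_PASS_FRACTION,
    probes: list[str] | None = None,
) -> QcReport:
    """Remove samples whose probe pass-rate falls below threshold.

    Pass-rates are computed on ``probes`` (normally the probe-filter
    survivors); a probe passes when detp < pass_alpha, and a sample is
    removed when its pass fraction is strictly below ``min_pass_fraction``.
    """
    _check_matrix(detp)
    sub = detp if probes is None else detp.loc[probes]
    if sub.shape[0] == 0:
        raise QcError("no probes left to evaluate sample pass-rates on")
    pass_frac = (sub.to_numpy() < pass_alpha).sum(axis=0) / sub.shape[0]
    bad = pass_frac < min_pass_fraction
    return QcReport(
        retained_probes=sub.index.tolist(),
        excluded_probes={},
        retained_samples=sub.columns[~bad].tolist(),
        excluded_samples=dict(zip(sub.columns[bad], pass_frac[bad].astype(float))),
        thresholds={"pass_alpha": pass_alpha, "min_pass_fraction": min_pass_fraction},
    )


def run_qc(
    detp: pd.DataFrame,
    fail_alpha: float = PROBE_FAIL_ALPHA,
    max_fail_fraction: float = PROBE_MAX_FAIL_FRACTION,
    pass_alpha: float = SAMPLE_PASS_ALPHA,
    min_pass_fraction: float = SAMPLE_MIN_PASS_FRACTION,
) -> QcReport:
    """Probe filter, then sample filter on the retained probes."""
    probe_part = filter_probes(detp, fail_alpha, max_fail_fraction)
    sample_part = filter_samples(
        detp, pass_alpha, min_pass_fraction, probes=probe_part.retained_probes
    )
    report = QcReport(
        retained_probes=probe_part.retained_probes,
        excluded_probes=probe_part.excluded_probes,
        retained_samples=sample_part.retained_samples,
        excluded_samples=sample_part.excluded_samples,
        thresholds={**probe_part.thresholds, **sample_part.thresholds},
    )
    logger.info("QC: %s", report.summary())
    return report


def apply_qc(
    beta: pd.DataFrame,
    report: QcReport,
    blocklist: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Restrict a beta matrix to QC survivors minus a probe blocklist.

    Row and column order of the input is preserved. Blocklist ids absent
    from the matrix trigger a warning and are ignored.
    """
    missing_p = set(report.retained_probes) - set(beta.index)
    missing_s = set(report.retained_samples) - set(beta.columns)
    if missing_p or missing_s:
        raise QcError(
            f"QC report does not match matrix ids: {len(missing_p)} probes / "
            f"{len(missing_s)} samples unknown"
        )
    unknown = set(blocklist) - set(beta.index)
    if unknown:
        warnings.warn(
            f"{len(unknown)} blocklist ids absent from the beta matrix were "
            f"ignored (e.g. {sorted(unknown)[:3]})",
            stacklevel=2,
        )
    drop = set(blocklist)
    retained_p = set(report.retained_probes)
    retained_s = set(report.retained_samples)
    keep_probes = [p for p in beta.index if p in retained_p and p not in drop]
    keep_samples = [s for s in beta.columns if s in retained_s]
    return beta.loc[keep_probes, keep_samples]


def report_to_frame(report: QcReport) -> pd.DataFrame:
    """Flatten a QcReport into a long TSV-friendly table."""
    rows = [("probe", p, "retained", "") for p in report.retained_probes]
    rows += [("probe", p, "excluded", r) for p, r in report.excluded_probes.items()]
    rows += [("sample", s, "retained", "") for s in report.retained_samples]
    rows += [
        ("sample", s, "excluded", f"pass_rate={v:.4f}")
        for s, v in report.excluded_samples.items()
    ]
    return pd.DataFrame(rows, columns=["level", "id", "status", "detail"])
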