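"""Per-study effect sizes and within-study variances.

Converts raw study summaries (continuous two-arm summaries or dichotomous
2x2 tables) into effect estimates on the analysis scale.  Ratio measures
(odds ratio, risk ratio, Peto odds ratio) are kept on the log scale so that
downstream pooling can use normal theory on an additive scale.

Rare-event handling for 2x2 tables follows standard Cochrane practice: a
continuity correction of +0.5 is added to all four cells when any cell is
zero (ratio measures only), and studies with zero events in both arms are
excluded for ratio measures but retained for the risk difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
DICHOTOMOUS = "dichotomous"
PRECOMPUTED = "precomputed"

#: Effect measures on the analysis scale.
MEASURES = ("MD", "SMD", "logOR", "logRR", "RD", "logPetoOR")


class InvalidRecordError(ValueError):
    """A study record violates the preconditions of its design."""


class DegenerateStudyError(ValueError):
    """A study carries no usable information (e.g. zero SD in both arms)."""


@dataclass
class StudyRecord:
    """Raw per-study summaries.

    Exactly one family of fields is used depending on ``design``:

    * ``continuous`` — per-arm ``n``, ``mean``, ``sd``;
    * ``dichotomous`` — per-arm events and totals, giving the 2x2 cells
      ``a`` (arm-1 events), ``b`` (arm-1 non-events), ``c`` (arm-2 events),
      ``d`` (arm-2 non-events);
    * ``precomputed`` — an effect and its variance on the analysis scale.

    ``n_total`` is the number of subjects in the study; it is only required
    by estimators that weight by study size.
    """

    study_id: str
    design: str
    n1: Optional[float] = None
    mean1: Optional[float] = None
    sd1: Optional[float] = None
    n2: Optional[float] = None
    mean2: Optional[float] = None
    sd2: Optional[float] = None
    events1: Optional[int] = None
    total1: Optional[int] = None
    events2: Optional[int] = None
    total2: Optional[int] = None
    effect: Optional[float] = None
    variance: Optional[float] = None
    n_total: Optional[int] = None

    def __post_init__(self) -> None:
        if self.design not in (CONTINUOUS, DICHOTOMOUS, PRECOMPUTED):
            raise InvalidRecordError(f"unknown design {self.design!r}")
        if self.design == DICHOTOMOUS:
            for ev, tot in ((self.events1, self.total1), (self.events2, self.total2)):
                if ev is None or tot is None or tot < 1 or not 0 <= ev <= tot:
                    raise InvalidRecordError(
                        f"study {self.study_id}: events must satisfy 0 <= events <= total, total >= 1"
                    )
            if self.n_total is None:
                self.n_total = int(self.total1 + self.total2)
        elif self.design == CONTINUOUS:
            if any(v is None for v in (self.n1, self.mean1, self.sd1, self.n2, self.mean2, self.sd2)):
                raise InvalidRecordError(f"study {self.study_id}: incomplete continuous arms")
            if self.n1 < 2 or self.n2 < 2:
                raise InvalidRecordError(f"study {self.study_id}: n >= 2 required per arm")
            if self.sd1 < 0 or self.sd2 < 0:
                raise InvalidRecordError(f"study {self.study_id}: negative SD")
            if self.n_total is None:
                self.n_total = int(self.n1 + self.n2)
        else:
            if self.effect is None or self.variance is None or self.variance <= 0:
                raise InvalidRecordError(
                    f"study {self.study_id}: precomputed design needs effect and variance > 0"
                )

    @property
    def cells(self) -> tuple[float, float, float, float]:
        """2x2 cells (a, b, c, d) for a dichotomous record."""
        if self.design != DICHOTOMOUS:
            raise InvalidRecordError("cells only defined for dichotomous records")
        a = float(self.events1)
        c = float(self.events2)
        return a, float(self.total1) - a, c, float(self.total2) - c


@dataclass
class EffectEstimate:
    """A per-study effect estimate with its within-study variance.

    ``theta_hat`` is on the analysis scale (log scale for ratio measures)
    and ``sigma2_hat`` is treated as known in all downstream models.
    """

    theta_hat: float
    sigma2_hat: float
    measure: str
    study_id: str = ""
    n_total: Optional[int] = None
    excluded: bool = False
    reason: str = ""


def _needs_continuity(a: float, b: float, c: float, d: float) -> bool:
    return min(a, b, c, d) == 0


def effect_continuous(record: StudyRecord, measure: str = "MD") -> EffectEstimate:
    """Mean difference or (Hedges-corrected) standardised mean difference.

    The SMD uses the small-sample corrected Hedges *g* with the variance
    approximation ``N/(n1*n2) + g^2 / (2*(N - 3.94))`` used by standard
    systematic-review software.
    """
    if record.design != CONTINUOUS:
        raise InvalidRecordError("effect_continuous requires a continuous record")
    n1, m1, s1 = record.n1, record.mean1, record.sd1
    n2, m2, s2 = record.n2, record.mean2, record.sd2
    if s1 == 0 and s2 == 0:
        raise DegenerateStudyError(f"study {record.study_id}: zero SD in both arms")
    if measure == "MD":
        theta = m1 - m2
        var = s1 ** 2 / n1 + s2 ** 2 / n2
    elif measure == "SMD":
        big_n = n1 + n2
        df = big_n - 2
        s_pooled = math.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df)
        if s_pooled == 0:
            raise DegenerateStudyError(f"study {record.study_id}: zero pooled SD")
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = j * (m1 - m2) / s_pooled
        theta = g
        var = big_n / (n1 * n2) + g ** 2 / (2.0 * (big_n - 3.94))
    else:
        raise ValueError(f"unsupported continuous measure {measure!r}")
    return EffectEstimate(theta, var, measure, record.study_id, record.n_total)


def effect_dichotomous(
    record: StudyRecord, measure: str = "logOR", continuity: float = 0.5
) -> EffectEstimate:
    """Log odds ratio, log risk ratio or risk difference from a 2x2 table.

    When any cell is zero, ``continuity`` is added to all four cells for the
    ratio measures; the risk difference is computed from the raw counts.
    Double-zero (or double-full for OR) studies are flagged ``excluded`` for
    ratio measures since their effect is undefined; they are retained for RD.
    """
    if record.design != DICHOTOMOUS:
        raise InvalidRecordError("effect_dichotomous requires a dichotomous record")
    a, b, c, d = record.cells

    if measure == "RD":
        p1 = a / (a + b)
        p2 = c / (c + d)
        theta = p1 - p2
        var = p1 * (1 - p1) / (a + b) + p2 * (1 - p2) / (c + d)
        if var == 0:
            # all-zero or all-events tables carry no sampling variability on
            # the risk scale; keep the study but flag it
            return EffectEstimate(theta, var, measure, record.study_id,
                                  record.n_total, excluded=True,
                                  reason="zero variance (degenerate margins)")
        return EffectEstimate(theta, var, measure, record.study_id, record.n_total)

    if measure not in ("logOR", "logRR"):
        raise ValueError(f"unsupported dichotomous measure {measure!r}")

    if (a == 0 and c == 0) or (b == 0 and d == 0):
        return EffectEstimate(
            float("nan"), float("nan"), measure, record.study_id, record.n_total,
            excluded=True, reason="no events (or no non-events) in either arm",
        )
    if _needs_continuity(a, b, c, d):
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
    if measure == "logOR":
        theta = math.log(a * d / (b * c))
        var = 1 / a + 1 / b + 1 / c + 1 / d
    else:
        theta = math.log((a / (a + b)) / (c / (c + d)))
        var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    return EffectEstimate(theta, var, measure, record.study_id, record.n_total)


def peto_components(record: StudyRecord) -> tuple[float, float]:
    """Peto one-step quantities ``(O - E, V)`` for a 2x2 table.

    ``O = a``, ``E = (a+b)(a+c)/N`` and the hypergeometric variance
    ``V = (a+b)(c+d)(a+c)(b+d) / (N^2 (N-1))``.  The per-study log Peto odds
    ratio is ``(O - E)/V`` with variance ``1/V``.  Raises on empty margins
    (``V = 0``) since such tables carry no information about the odds ratio.
    """
    if record.design != DICHOTOMOUS:
        raise InvalidRecordError("peto_components requires a dichotomous record")
    a, b, c, d = record.cells
    n = a + b + c + d
    if n < 2:
        raise DegenerateStudyError(f"study {record.study_id}: fewer than 2 subjects")
    v = (a + b) * (c + d) * (a + c) * (b + d) / (n ** 2 * (n - 1))
    if v == 0:
        raise DegenerateStudyError(f"study {record.study_id}: empty margin (V = 0)")
    o_minus_e = a - (a + b) * (a + c) / n
    return o_minus_e, v


def effect_peto(record: StudyRecord) -> EffectEstimate:
    """Per-study log Peto odds ratio as an EffectEstimate (variance 1/V)."""
    try:
        o_minus_e, v = peto_components(record)
    except DegenerateStudyError as exc:
        return EffectEstimate(float("nan"), float("nan"), "logPetoOR",
                              record.study_id, record.n_total,
                              excluded=True, reason=str(exc))
    return EffectEstimate(o_minus_e / v, 1.0 / v, "logPetoOR",
                          record.study_id, record.n_total)


def compute_effects(records: Sequence[StudyRecord], measure: str,
                    continuity: float = 0.5) -> list[EffectEstimate]:
    """Dispatch each record to the right effect-size routine for ``measure``."""
    out: list[EffectEstimate] = []
    for rec in records:
        if rec.design == PRECOMPUTED:
            out.append(EffectEstimate(rec.effect, rec.variance, measure,
                                      rec.study_id, rec.n_total))
        elif measure in ("MD", "SMD"):
            out.append(effect_continuous(rec, measure))
        elif measure == "logPetoOR":
            out.append(effect_peto(rec))
        else:
            out.append(effect_dichotomous(rec, measure, continuity))
    return out


def included(effects: Iterable[EffectEstimate]) -> list[EffectEstimate]:
    return [e for e in effects if not e.excluded]


def as_arrays(effects: Iterable[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    """(theta_hat, sigma2_hat) arrays over non-excluded studies."""
    kept = included(effects)
    theta = np.array([e.theta_hat for e in kept], dtype=float)
    sigma2 = np.array([e.sigma2_hat for e in kept], dtype=float)
    return theta, sigma2


def read_study_csv(path) -> list[StudyRecord]:
    """Read study records from CSV (one row per study, header required).

    Recognised columns: ``study_id``, ``design``, continuous arms
    ``n1,mean1,sd1,n2,mean2,sd2``, dichotomous arms ``events1,total1,
    events2,total2`` (aliases ``a,n1,c,n2`` where ``design`` disambiguates),
    ``effect``, ``variance``, ``n_total``.
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        design = str(row["design"]).strip()
        get = lambda col: (None if col not in df.columns or pd.isna(row[col]) else row[col])
        if design == DICHOTOMOUS:
            events1 = get("events1") if get("events1") is not None else get("a")
            events2 = get("events2") if get("events2") is not None else get("c")
            total1 = get("total1") if get("total1") is not None else get("n1")
            total2 = get("total2") if get("total2") is not None else get("n2")
            rec = StudyRecord(
                study_id=str(row["study_id"]), design=design,
                events1=int(events1), total1=int(total1),
                events2=int(events2), total2=int(total2),
                n_total=None if get("n_total") is None else int(get("n_total")),
            )
        elif design == CONTINUOUS:
            rec = StudyRecord(
                study_id=str(row["study_id"]), design=design,
                n1=float(get("n1")), mean1=float(get("mean1")), sd1=float(get("sd1")),
                n2=float(get("n2")), mean2=float(get("mean2")), sd2=float(get("sd2")),
                n_total=None if get("n_total") is None else int(get("n_total")),
            )
        else:
            rec = StudyRecord(
                study_id=str(row["study_id"]), design=PRECOMPUTED,
                effect=float(get("effect")), variance=float(get("variance")),
                n_total=None if get("n_total") is None else int(get("n_total")),
            )
        records.append(rec)
    return records
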