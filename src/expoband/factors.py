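"""Near-field semi-quantitative exposure scoring.

The model rates an exposure situation (a job task performed under given
working conditions) by twelve modifying factors: position factor (P_f),
potential emission and handling (E_p), historical exposure (E_h), type of
process with tool cleaning/inspection/maintenance (E_m), general
ventilation and containment (eta_gv), localized control measures (L_c),
personal protective equipment (PPE), health-hazard category (H), task
duration (T_h), task frequency (T_f), distance from the source (D), and
room volume (V).  Each factor is classified into one of a small number of
defined classes, each carrying a dimensionless score in [1.0, 10.0].  The
exposure score is the natural log of the product of the eleven multiplier
scores divided by the room-volume score::

    score = ln( P_f * (E_p*E_h*E_m) * (eta_gv*L_c*PPE) * H * (T_h*T_f*D) / V )

and is banded into four exposure categories (1 = no exposure, 2 = low,
3 = medium, 4 = high).  The score table is data, not code: it ships as a
versioned YAML config so the calibration can be revised without a code
change.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "FACTOR_IDS",
    "MULTIPLIER_IDS",
    "Classification",
    "FactorSpec",
    "FactorTable",
    "SituationProfile",
    "ScoreResult",
    "CategoryBands",
    "Band",
    "FactorTableError",
    "UnknownLabelError",
    "load_factor_table",
    "load_category_bands",
    "lookup_factor_score",
    "compute_exposure_score",
    "assign_category",
    "max_attainable_score",
    "enumerate_attainable_log_scores",
    "score_breakdown_report",
]

#: Factor identifiers in the order they enter the scoring formula.
FACTOR_IDS: tuple[str, ...] = (
    "position_factor",
    "potential_emission",
    "historical_exposure",
    "process_type",
    "ventilation_containment",
    "localized_control",
    "ppe",
    "health_hazard",
    "task_duration",
    "task_frequency",
    "distance",
    "room_volume",
)

MULTIPLIER_IDS: tuple[str, ...] = FACTOR_IDS[:-1]

PHASES = ("liquid", "solid")

#: Score reported when every factor sits at its no-exposure class.
NO_EXPOSURE_SCORE = 1.00
#: Lower clamp for any profile that is not entirely no-exposure, so that
#: every non-trivial situation lands in category >= 2.
MIN_NONTRIVIAL_SCORE = 1.01


class FactorTableError(ValueError):
    """Raised when a factor table violates its structural invariants."""


class UnknownLabelError(KeyError):
    """Raised when a profile selection does not match any classification."""

    def __init__(self, factor_id: str, label: str, valid: Iterable[str]):
        self.factor_id = factor_id
        self.label = label
        self.valid = list(valid)
        super().__init__(
            f"unknown classification {label!r} for factor {factor_id!r}; "
            f"valid labels: {self.valid}"
        )


_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


def normalize_label(label: str) -> str:
    """Case-insensitive, whitespace-collapsed canonical form of a label.

    Unicode dashes map to ``-``, ``≤``/``≥`` to ``<=``/``>=`` and the cubed
    sign to ``3`` so that labels typed on a plain keyboard match the table.
    """
    s = str(label).translate(_DASHES)
    s = s.replace("≤", "<=").replace("≥", ">=").replace("³", "3")
    return re.sub(r"\s+", " ", s).strip().lower()


@dataclass(frozen=True)
class Classification:
    label: str
    score: float
    phase: str | None = None
    aliases: tuple[str, ...] = ()
    no_exposure: bool = False

    def matches(self, label: str) -> bool:
        key = normalize_label(label)
        return key == normalize_label(self.label) or any(
            key == normalize_label(a) for a in self.aliases
        )


@dataclass(frozen=True)
class FactorSpec:
    """One modifying factor: its role in the formula and its classes."""

    factor_id: str
    role: str  # "multiplier" or "divisor"
    classifications: tuple[Classification, ...]
    phase_dependent: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("multiplier", "divisor"):
            raise FactorTableError(
                f"factor {self.factor_id!r}: role must be multiplier or "
                f"divisor, got {self.role!r}"
            )
        if not self.classifications:
            raise FactorTableError(f"factor {self.factor_id!r} has no classifications")
        for c in self.classifications:
            if not (1.0 <= c.score <= 10.0):
                raise FactorTableError(
                    f"factor {self.factor_id!r}, class {c.label!r}: score "
                    f"{c.score} outside [1.0, 10.0]"
                )
            if self.phase_dependent and c.phase not in PHASES:
                raise FactorTableError(
                    f"factor {self.factor_id!r}, class {c.label!r}: "
                    f"phase-dependent factor needs phase in {PHASES}"
                )
        for phase in (PHASES if self.phase_dependent else (None,)):
            seen: set[str] = set()
            for c in self._classes(phase):
                key = normalize_label(c.label)
                if key in seen:
                    raise FactorTableError(
                        f"factor {self.factor_id!r}: duplicate classification "
                        f"label {c.label!r}"
                    )
                seen.add(key)
        if self.phase_dependent:
            sets = {p: sorted(c.score for c in self._classes(p)) for p in PHASES}
            if sets["liquid"] != sets["solid"]:
                raise FactorTableError(
                    f"factor {self.factor_id!r}: liquid and solid score sets "
                    f"differ: {sets}"
                )
        n_noexp = sum(c.no_exposure for c in self.classifications)
        if self.phase_dependent:
            # one flagged class overall; its solid twin shares label and score
            pass
        if n_noexp != 1:
            raise FactorTableError(
                f"factor {self.factor_id!r}: expected exactly one class "
                f"flagged no_exposure, found {n_noexp}"
            )
        flagged = next(c for c in self.classifications if c.no_exposure)
        if flagged.score != 1.0:
            raise FactorTableError(
                f"factor {self.factor_id!r}: no-exposure class {flagged.label!r} "
                f"must score 1.0, got {flagged.score}"
            )

    def _classes(self, phase: str | None) -> tuple[Classification, ...]:
        if not self.phase_dependent:
            return self.classifications
        if phase not in PHASES:
            raise ValueError(
                f"factor {self.factor_id!r} is phase-dependent; "
                f"phase must be one of {PHASES}, got {phase!r}"
            )
        return tuple(c for c in self.classifications if c.phase == phase)

    def labels(self, phase: str | None = None) -> list[str]:
        return [c.label for c in self._classes(phase if self.phase_dependent else None)]

    def find(self, label: str, phase: str | None = None) -> Classification:
        classes = self._classes(phase if self.phase_dependent else None)
        for c in classes:
            if c.matches(label):
                return c
        raise UnknownLabelError(self.factor_id, label, (c.label for c in classes))

    def scores(self, phase: str | None = None) -> np.ndarray:
        return np.unique([c.score for c in self._classes(phase)])

    def is_no_exposure(self, label: str, phase: str | None = None) -> bool:
        """True if ``label`` names the factor's no-exposure class.

        For phase-dependent factors the no-exposure label is shared between
        phases, so matching by label (not by flag) is intentional.
        """
        flagged = next(c for c in self.classifications if c.no_exposure)
        return flagged.matches(label) or self.find(label, phase).matches(flagged.label)


@dataclass(frozen=True)
class FactorTable:
    """The complete, validated modifying-factor score lookup."""

    factors: tuple[FactorSpec, ...]
    version: str = "unversioned"
    source: str = ""

    def __post_init__(self) -> None:
        ids = [f.factor_id for f in self.factors]
        missing = [fid for fid in FACTOR_IDS if fid not in ids]
        extra = [fid for fid in ids if fid not in FACTOR_IDS]
        if missing or extra:
            raise FactorTableError(
                f"factor table must contain exactly {FACTOR_IDS}; "
                f"missing={missing} unexpected={extra}"
            )
        for f in self.factors:
            if (f.role == "divisor") != (f.factor_id == "room_volume"):
                raise FactorTableError(
                    f"room_volume is the only divisor factor; "
                    f"{f.factor_id!r} has role {f.role!r}"
                )
            if f.phase_dependent and f.factor_id != "potential_emission":
                raise FactorTableError(
                    f"only potential_emission is phase-dependent, not "
                    f"{f.factor_id!r}"
                )

    def factor(self, factor_id: str) -> FactorSpec:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(f"unknown factor {factor_id!r}; known: {FACTOR_IDS}")

    @property
    def divisor(self) -> FactorSpec:
        return self.factor("room_volume")


@dataclass(frozen=True)
class SituationProfile:
    """One classification selection per factor for a job/task situation."""

    situation_id: str
    phase: str
    selections: Mapping[str, str]
    task_label: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        missing = [fid for fid in FACTOR_IDS if fid not in self.selections]
        extra = [fid for fid in self.selections if fid not in FACTOR_IDS]
        if missing or extra:
            raise ValueError(
                f"profile {self.situation_id!r} must select exactly one class "
                f"per factor; missing={missing} unexpected={extra}"
            )


@dataclass(frozen=True)
class BreakdownEntry:
    factor_id: str
    label: str
    score: float
    log_contribution: float  # negative for the divisor


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one situation profile.

    ``log_score`` is the plain ln of the raw product; ``score`` is the
    reported score after the no-exposure convention (1.00 when every factor
    is at its no-exposure class) and the lower clamp at 1.01 for any other
    profile.  ``clamped`` flags when the clamp was applied.
    """

    situation_id: str
    raw_product: float
    log_score: float
    score: float
    category: int
    breakdown: tuple[BreakdownEntry, ...]
    clamped: bool = False

    @property
    def score_2dp(self) -> float:
        return round_half_up(self.score)


@dataclass(frozen=True)
class Band:
    category: int
    lower: float
    upper: float
    description: str = ""


@dataclass(frozen=True)
class CategoryBands:
    bands: tuple[Band, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        cats = [b.category for b in self.bands]
        if cats != sorted(cats) or len(set(cats)) != len(cats):
            raise ValueError("bands must be sorted by category and unique")
        for b in self.bands:
            if b.upper < b.lower:
                raise ValueError(f"band {b.category}: upper < lower")
        for lo, hi in zip(self.bands, self.bands[1:]):
            # contiguity at the printed 2-dp resolution
            if abs(hi.lower - lo.upper - 0.01) > 1e-9:
                raise ValueError(
                    f"bands {lo.category} and {hi.category} are not "
                    f"contiguous at 2 decimals"
                )

    @property
    def max_score(self) -> float:
        return self.bands[-1].upper


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed score tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# config loading


def _default_resource(name: str):
    return resources.files("expoband.data") / name


def load_factor_table(path: str | Path | None = None) -> FactorTable:
    """Load and validate a factor table from YAML (default: packaged table)."""
    src = Path(path) if path is not None else _default_resource("factor_table.yaml")
    with (open(src) if isinstance(src, Path) else src.open()) as fh:
        doc = yaml.safe_load(fh)
    try:
        factors = []
        for fd in doc["factors"]:
            classes = tuple(
                Classification(
                    label=str(cd["label"]),
                    score=float(cd["score"]),
                    phase=cd.get("phase"),
                    aliases=tuple(cd.get("aliases", ())),
                    no_exposure=bool(cd.get("no_exposure", False)),
                )
                for cd in fd["classifications"]
            )
            factors.append(
                FactorSpec(
                    factor_id=str(fd["id"]),
                    role=str(fd.get("role", "multiplier")),
                    classifications=classes,
                    phase_dependent=bool(fd.get("phase_dependent", False)),
                )
            )
        return FactorTable(
            factors=tuple(factors),
            version=str(doc.get("version", "unversioned")),
            source=str(doc.get("source", "")),
        )
    except KeyError as exc:
        raise FactorTableError(f"factor table config is missing key {exc}") from exc


def load_category_bands(path: str | Path | None = None) -> CategoryBands:
    src = Path(path) if path is not None else _default_resource("category_bands.yaml")
    with (open(src) if isinstance(src, Path) else src.open()) as fh:
        doc = yaml.safe_load(fh)
    bands = tuple(
        Band(
            category=int(b["category"]),
            lower=float(b["lower"]),
            upper=float(b["upper"]),
            description=str(b.get("description", "")),
        )
        for b in doc["bands"]
    )
    return CategoryBands(bands=bands, version=str(doc.get("version", "unversioned")))


# ---------------------------------------------------------------------------
# scoring


def lookup_factor_score(
    table: FactorTable,
    factor_id: str,
    label: str,
    phase: str | None = None,
) -> float:
    """Score of one classification, matched case- and whitespace-insensitively."""
    return table.factor(factor_id).find(label, phase).score


def compute_exposure_score(
    table: FactorTable,
    profile: SituationProfile,
    bands: CategoryBands | None = None,
) -> ScoreResult:
    """Score a situation profile.

    The raw product multiplies the eleven multiplier-factor scores and
    divides by the room-volume score; the reported score is its natural
    log, subject to the no-exposure convention (all factors at their
    no-exposure class -> score 1.00, category 1) and the lower clamp at
    1.01 for any other profile.
    """
    if bands is None:
        bands = load_category_bands()
    entries = []
    raw = 1.0
    all_no_exposure = True
    for fid in FACTOR_IDS:
        spec = table.factor(fid)
        phase = profile.phase if spec.phase_dependent else None
        cls = spec.find(profile.selections[fid], phase)
        sign = -1.0 if spec.role == "divisor" else 1.0
        raw *= cls.score**sign
        entries.append(
            BreakdownEntry(fid, cls.label, cls.score, sign * math.log(cls.score))
        )
        if not spec.is_no_exposure(cls.label, phase):
            all_no_exposure = False
    log_score = math.log(raw)
    clamped = False
    if all_no_exposure:
        score = NO_EXPOSURE_SCORE
    elif log_score < MIN_NONTRIVIAL_SCORE:
        score, clamped = MIN_NONTRIVIAL_SCORE, True
    else:
        score = log_score
    category = assign_category(bands, score)
    return ScoreResult(
        situation_id=profile.situation_id,
        raw_product=raw,
        log_score=log_score,
        score=score,
        category=category,
        breakdown=tuple(entries),
        clamped=clamped,
    )


def assign_category(bands: CategoryBands, score: float, tol: float = 0.005) -> int:
    """Band a score after half-up rounding to 2 decimals.

    Scores above the top band's upper limit (plus rounding tolerance) are
    rejected as inconsistent with the factor table that defined the bands.
    """
    s = round_half_up(score)
    if s < bands.bands[0].lower - tol:
        raise ValueError(f"score {score} below the lowest band")
    for b in bands.bands:
        if b.lower - 1e-9 <= s <= b.upper + 1e-9:
            return b.category
    if s > bands.max_score:
        raise ValueError(
            f"score {score} exceeds the maximum attainable score "
            f"{bands.max_score}; profile inconsistent with the factor table"
        )
    # 2-dp rounding makes the bands contiguous, so this is unreachable
    raise ValueError(f"score {score} falls outside all bands")  # pragma: no cover


def max_attainable_score(table: FactorTable) -> float:
    """ln of (product of per-factor maxima / minimum divisor score)."""
    log_max = 0.0
    for f in table.factors:
        scores = f.scores("liquid" if f.phase_dependent else None)
        log_max += -math.log(scores.min()) if f.role == "divisor" else math.log(scores.max())
    return log_max


def enumerate_attainable_log_scores(table: FactorTable, phase: str = "liquid") -> np.ndarray:
    """Every attainable ln(raw product), by exhaustive product-set enumeration.

    Walks the factors accumulating the set of attainable log products
    (deduplicated at 1e-9), which enumerates all classification
    combinations without materialising the full cartesian product.  Used
    as the brute-force oracle for the score bounds.
    """
    logs = np.array([0.0])
    for f in table.factors:
        contrib = np.log(f.scores(phase if f.phase_dependent else None))
        if f.role == "divisor":
            contrib = -contrib
        logs = np.unique(np.round((logs[:, None] + contrib[None, :]).ravel(), 9))
    return logs


def score_breakdown_report(result: ScoreResult) -> str:
    """Human-readable per-factor contribution table for one scored profile."""
    lines = [
        f"situation: {result.situation_id}",
        f"{'factor':<24} {'score':>6} {'ln-contribution':>16}",
    ]
    for e in result.breakdown:
        lines.append(f"{e.factor_id:<24} {e.score:>6.2f} {e.log_contribution:>+16.4f}")
    total = sum(e.log_contribution for e in result.breakdown)
    lines.append(f"{'ln(raw product)':<24} {'':>6} {total:>+16.4f}")
    lines.append(
        f"reported score {result.score_2dp:.2f} "
        f"(category {result.category}{', clamped' if result.clamped else ''})"
    )
    return "\n".join(lines)
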