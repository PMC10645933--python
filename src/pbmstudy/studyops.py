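"""Study-design utilities: blinded sex-balanced randomization, light-dose
arithmetic, and the fur-attenuation computation.

A blinded study assigns each animal a neutral code; the code→group map
stays sealed until analysis is complete.  The dose arithmetic converts a
pulsed-light prescription (peak irradiance, pulse rate, duty cycle,
session length) into average irradiance and per-session / cumulative
fluence.  Fur attenuation compares transmitted power through shaved vs
unshaved head preparations at matched source powers.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

__all__ = [
    "DoseSpec",
    "Codebook",
    "BlindingError",
    "randomize_groups",
    "dose_summary",
    "fur_attenuation",
]


@dataclass
class DoseSpec:
    """One treatment arm's pulsed-light prescription.

    Defaults reflect a standard transcranial protocol: 810 nm light
    pulsed at 100 Hz with a 20% duty cycle, 120 s sessions three times a
    week.  ``peak_irradiance_mw_cm2`` distinguishes the arms (e.g. 600
    for a high-power arm, 6 for a low-power arm, 0 for sham).
    """

    peak_irradiance_mw_cm2: float
    wavelength_nm: float = 810.0
    pulse_rate_hz: float = 100.0
    duty_cycle: float = 0.2
    session_s: float = 120.0
    sessions_per_week: int = 3
    duration_weeks: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError("duty_cycle must be in (0, 1]")
        for name in ("wavelength_nm", "pulse_rate_hz", "session_s",
                     "sessions_per_week", "duration_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_irradiance_mw_cm2 < 0:
            raise ValueError("peak irradiance cannot be negative")


def dose_summary(spec: DoseSpec) -> dict[str, float]:
    """Average irradiance and fluence for a pulsed prescription.

    average irradiance (mW/cm²) = peak × duty cycle;
    per-session fluence (J/cm²) = average × session seconds / 1000;
    cumulative fluence = per-session × sessions/week × weeks.
    """
    avg = spec.peak_irradiance_mw_cm2 * spec.duty_cycle
    per_session = avg * spec.session_s / 1000.0
    cumulative = per_session * spec.sessions_per_week * spec.duration_weeks
    return {
        "average_irradiance_mw_cm2": avg,
        "per_session_fluence_j_cm2": per_session,
        "cumulative_fluence_j_cm2": cumulative,
    }


def fur_attenuation(
    power_shaved_mw: list[float], power_unshaved_mw: list[float]
) -> dict[str, float]:
    """Transmission through the unshaved vs shaved preparation.

    Per matched pair, transmission % = unshaved / shaved × 100; reports
    mean ± s.d. transmission and attenuation = 100 − mean transmission.
    """
    shaved = np.asarray(power_shaved_mw, dtype=float)
    unshaved = np.asarray(power_unshaved_mw, dtype=float)
    if shaved.shape != unshaved.shape or shaved.size == 0:
        raise ValueError("need equal-length non-empty paired measurements")
    if np.any(shaved <= 0):
        raise ValueError("shaved reference power must be positive")
    trans = unshaved / shaved * 100.0
    mean = float(trans.mean())
    sd = float(trans.std(ddof=1)) if trans.size > 1 else 0.0
    return {
        "transmission_pct_mean": mean,
        "transmission_pct_sd": sd,
        "attenuation_pct": 100.0 - mean,
        "n_pairs": int(trans.size),
    }


# ---------------------------------------------------------------------------
# Blinding
# ---------------------------------------------------------------------------


class BlindingError(RuntimeError):
    """Group identity was requested before unblinding."""


@dataclass
class Codebook:
    """Blinding codebook: public id→code map plus a sealed code→group map.

    The group of a code is inaccessible until :meth:`unblind` is called;
    every unblinding event is recorded in the audit log.  The public and
    sealed halves persist as separate JSON files so the blind survives
    process restarts.
    """

    code_of: dict[str, str]
    _sealed: dict[str, str]
    unblinded: bool = False
    audit_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.code_of.values())) != len(self.code_of):
            raise ValueError("id→code map must be a bijection")

    @property
    def codes(self) -> list[str]:
        return sorted(self.code_of.values())

    def unblind(self, actor: str = "analyst", reason: str = "") -> None:
        self.unblinded = True
        self.audit_log.append(
            {
                "event": "unblind",
                "actor": actor,
                "reason": reason,
                "time": datetime.now(timezone.utc).isoformat(),
            }
        )

    def group_of(self, code: str) -> str:
        if not self.unblinded:
            raise BlindingError(
                "codebook is sealed: call unblind() after data collection "
                "and processing are complete"
            )
        return self._sealed[code]

    def assignment(self) -> dict[str, str]:
        """Full mouse-id → group map (requires unblinding)."""
        return {mid: self.group_of(code) for mid, code in self.code_of.items()}

    # -- persistence --------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        public = {"code_of": self.code_of, "audit_log": self.audit_log,
                  "unblinded": self.unblinded}
        (directory / "codebook_public.json").write_text(json.dumps(public, indent=2))
        (directory / "codebook_sealed.json").write_text(json.dumps(self._sealed, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Codebook":
        directory = Path(directory)
        public = json.loads((directory / "codebook_public.json").read_text())
        sealed = json.loads((directory / "codebook_sealed.json").read_text())
        return cls(
            code_of=public["code_of"],
            _sealed=sealed,
            unblinded=public.get("unblinded", False),
            audit_log=public.get("audit_log", []),
        )


def _make_codes(n: int, rng: np.random.Generator) -> list[str]:
    alphabet = np.array(list(string.ascii_uppercase + string.digits))
    codes: set[str] = set()
    while len(codes) < n:
        codes.add("".join(rng.choice(alphabet, size=6)))
    return sorted(codes)


def randomize_groups(
    mice: list[tuple[str, str]],
    group_names: list[str],
    seed: int,
    group_sizes: dict[str, int] | None = None,
) -> Codebook:
    """Sex-balanced randomization into blinded groups.

    Within each sex, mice are shuffled and dealt to the groups in a
    random round-robin order, so per-sex group sizes differ by at most
    one.  Explicit unequal ``group_sizes`` (e.g. {19, 20, 21} totalling
    the cohort) are honoured while keeping sexes as balanced as the
    quotas allow.  Reproducible by seed.
    """
    if not mice:
        raise ValueError("no mice to randomize")
    if len({mid for mid, _ in mice}) != len(mice):
        raise ValueError("duplicate mouse ids")
    if group_sizes is not None:
        if set(group_sizes) != set(group_names):
            raise ValueError("group_sizes keys must match group_names")
        if sum(group_sizes.values()) != len(mice):
            raise ValueError("group_sizes must sum to the cohort size")
    rng = np.random.default_rng(seed)
    quota = dict(group_sizes) if group_sizes else {g: 0 for g in group_names}
    unlimited = group_sizes is None
    assignment: dict[str, str] = {}
    by_sex: dict[str, list[str]] = {}
    for mid, sex in mice:
        by_sex.setdefault(sex, []).append(mid)
    order = list(group_names)
    rng.shuffle(order)
    k = 0  # round-robin pointer shared across sexes keeps totals balanced
    for sex in sorted(by_sex):
        ids = sorted(by_sex[sex])
        rng.shuffle(ids)
        for mid in ids:
            for _ in range(len(order)):
                g = order[k % len(order)]
                k += 1
                if unlimited or quota[g] > 0:
                    if not unlimited:
                        quota[g] -= 1
                    assignment[mid] = g
                    break
    codes = _make_codes(len(mice), rng)
    ids_shuffled = sorted(assignment)
    rng.shuffle(ids_shuffled)
    code_of = dict(zip(ids_shuffled, codes))
    sealed = {code_of[mid]: assignment[mid] for mid in code_of}
    return Codebook(code_of=code_of, _sealed=sealed)
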