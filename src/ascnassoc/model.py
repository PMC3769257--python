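"""Allele-specific copy-number (ASCN) state space and analytic frequency model.

An ASCN state is the unordered multiset of SNP alleles an individual carries at
a locus inside a common CNV: NULL (zero copies), A, B, AA, AB, ..., up to four
copies (AAAA ... BBBB) — 15 states in total.  This module provides:

* the canonical state space and its ordering,
* control-population state frequencies derived from the frequencies of
  deleted / normal / duplicated chromosomes and the B allele frequency,
* a multiplicative two-parameter risk model (per-copy and per-B-allele
  relative risks) and the induced case-population state frequencies,
* the frequency- and risk-scenario grids of the simulation study.

States are phase-free: the risk attached to, say, ABB does not depend on how
the three copies are distributed over the two chromosomes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

MAX_CN = 4

#: cnv_type values accepted by :class:`ScenarioSpec`.
CNV_TYPES = ("del", "dup", "both")

_CNV_TYPE_ALIASES = {
    "del": "del",
    "deletions-only": "del",
    "deletion": "del",
    "deletions": "del",
    "dup": "dup",
    "duplications-only": "dup",
    "duplication": "dup",
    "duplications": "dup",
    "both": "both",
    "deletions-and-duplications": "both",
    "del+dup": "both",
}

# Normalization tolerance for probability distributions over states.
PROB_TOL = 1e-12


class InvalidScenarioError(ValueError):
    """Raised when scenario parameters fall outside their valid ranges."""


@dataclass(frozen=True, order=True)
class AscnState:
    """Unordered allele multiset at a SNP inside a CNV.

    Parameters
    ----------
    a_count, b_count
        Number of copies of the A and B allele.  Total copy number
        ``cn = a_count + b_count`` must lie in 0..4.  The zero-copy state is
        written "NULL".
    """

    a_count: int
    b_count: int

    def __post_init__(self) -> None:
        if self.a_count < 0 or self.b_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.cn > MAX_CN:
            raise ValueError(f"total copy number {self.cn} exceeds {MAX_CN}")

    @property
    def cn(self) -> int:
        """Total copy number (0-4)."""
        return self.a_count + self.b_count

    @property
    def label(self) -> str:
        """Human-readable label: "NULL", "A", "ABB", "AABB", ..."""
        if self.cn == 0:
            return "NULL"
        return "A" * self.a_count + "B" * self.b_count

    @classmethod
    def from_label(cls, label: str) -> "AscnState":
        label = label.strip().upper()
        if label in ("NULL", "-", ""):
            return cls(0, 0)
        if set(label) - {"A", "B"}:
            raise ValueError(f"unrecognized state label {label!r}")
        return cls(label.count("A"), label.count("B"))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_states() -> list[AscnState]:
    """The 15 ASCN states in canonical order (by copy number, then b_count)."""
    return [
        AscnState(cn - b, b) for cn in range(MAX_CN + 1) for b in range(cn + 1)
    ]


#: Canonical state list and label→index lookup, shared by all tables.
STATES: list[AscnState] = enumerate_states()
STATE_INDEX: dict[AscnState, int] = {s: i for i, s in enumerate(STATES)}
STATE_LABELS: list[str] = [s.label for s in STATES]


@dataclass(frozen=True)
class ScenarioSpec:
    """One point of the frequency grid.

    ``f_norm`` is the frequency of chromosomes carrying one copy of the CNV
    region; ``cnv_type`` says whether the population carries deletions only,
    duplications only, or both (with equal frequency); ``f_b`` is the B allele
    frequency.
    """

    f_norm: float
    cnv_type: str
    f_b: float

    def __post_init__(self) -> None:
        canon = _CNV_TYPE_ALIASES.get(str(self.cnv_type).lower())
        if canon is None:
            raise InvalidScenarioError(f"unknown cnv_type {self.cnv_type!r}")
        object.__setattr__(self, "cnv_type", canon)
        if not (0.0 < self.f_norm <= 1.0):
            raise InvalidScenarioError(
                f"f_norm must lie in (0, 1], got {self.f_norm}"
            )
        if not (0.0 < self.f_b < 1.0):
            raise InvalidScenarioError(f"f_b must lie in (0, 1), got {self.f_b}")

    def to_dict(self) -> dict:
        return {"f_norm": self.f_norm, "cnv_type": self.cnv_type, "f_b": self.f_b}


@dataclass(frozen=True)
class RiskModel:
    """Multiplicative disease risk model over ASCN states.

    ``rr_cn`` is the relative risk per extra total copy (reference CN=2);
    ``rr_allele`` the relative risk per extra B allele (reference zero B).
    The reference state is AA (RR = 1); (1, 1) is the global null.

    ``null_rr`` optionally overrides the risk of the NULL (zero-copy) state,
    which the multiplicative formula otherwise sets to ``rr_cn ** -2``.
    """

    rr_cn: float = 1.0
    rr_allele: float = 1.0
    null_rr: float | None = None

    def __post_init__(self) -> None:
        if self.rr_cn <= 0 or self.rr_allele <= 0:
            raise ValueError("relative risks must be positive")
        if self.null_rr is not None and self.null_rr <= 0:
            raise ValueError("null_rr must be positive")

    @property
    def is_null(self) -> bool:
        return self.rr_cn == 1.0 and self.rr_allele == 1.0

    def to_dict(self) -> dict:
        return {"rr_cn": self.rr_cn, "rr_allele": self.rr_allele}


class StateDistribution(Mapping[AscnState, float]):
    """Probability distribution over the 15 ASCN states.

    Behaves as a read-only mapping ``AscnState -> probability``; also exposes
    the probabilities as a vector aligned with :data:`STATES`.
    """

    def __init__(self, probs: Mapping[AscnState, float] | Iterable[float]):
        if isinstance(probs, Mapping):
            vec = [float(probs.get(s, 0.0)) for s in STATES]
        else:
            vec = [float(p) for p in probs]
            if len(vec) != len(STATES):
                raise ValueError(f"expected {len(STATES)} probabilities")
        if any(p < 0 for p in vec):
            raise ValueError("probabilities must be non-negative")
        total = sum(vec)
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        self._vec = tuple(vec)

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, state: AscnState) -> float:
        return self._vec[STATE_INDEX[state]]

    def __iter__(self):
        return iter(STATES)

    def __len__(self) -> int:
        return len(STATES)

    # vector access ---------------------------------------------------------
    def as_vector(self) -> list[float]:
        return list(self._vec)

    def to_frame(self) -> pd.DataFrame:
        """State table: columns state, a_count, b_count, cn, freq."""
        return pd.DataFrame(
            {
                "state": STATE_LABELS,
                "a_count": [s.a_count for s in STATES],
                "b_count": [s.b_count for s in STATES],
                "cn": [s.cn for s in STATES],
                "freq": self._vec,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StateDistribution":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls(
            {AscnState.from_label(r.state): r.freq for r in df.itertuples()}
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nz = {s.label: p for s, p in zip(STATES, self._vec) if p > 0}
        return f"StateDistribution({nz})"


# ---------------------------------------------------------------------------
# Frequency model
# ---------------------------------------------------------------------------

def chromosome_frequencies(spec: ScenarioSpec) -> tuple[float, float, float]:
    """Frequencies (f_del, f_norm, f_dup) of chromosomes carrying 0 / 1 / 2 copies.

    With a single CNV type the variant chromosome takes all of the remaining
    frequency 1 - f_norm; with both types, deletions and duplications are
    equally frequent: f_del = f_dup = (1 - f_norm) / 2.
    """
    rest = 1.0 - spec.f_norm
    if spec.cnv_type == "del":
        return rest, spec.f_norm, 0.0
    if spec.cnv_type == "dup":
        return 0.0, spec.f_norm, rest
    return rest / 2.0, spec.f_norm, rest / 2.0


def copy_number_distribution(spec: ScenarioSpec) -> list[float]:
    """P(CN = 0..4): random pairing of two chromosomes carrying 0/1/2 copies."""
    f_del, f_norm, f_dup = chromosome_frequencies(spec)
    return [
        f_del**2,
        2.0 * f_del * f_norm,
        f_norm**2 + 2.0 * f_del * f_dup,
        2.0 * f_norm * f_dup,
        f_dup**2,
    ]


def control_state_frequencies(spec: ScenarioSpec) -> StateDistribution:
    """Control-population ASCN state frequencies.

    Conditional on total copy number c, the number of B alleles is binomial
    (c, f_b): each copy carries an independent allele draw.  The NULL state
    receives all of P(CN=0).
    """
    p_cn = copy_number_distribution(spec)
    probs = {}
    for state in STATES:
        c, b = state.cn, state.b_count
        probs[state] = (
            p_cn[c]
            * math.comb(c, b)
            * spec.f_b**b
            * (1.0 - spec.f_b) ** (c - b)
        )
    return StateDistribution(probs)


def state_relative_risk(state: AscnState, risk: RiskModel) -> float:
    """RR(state) = rr_cn^(CN-2) * rr_allele^b, with AA as the reference.

    For the NULL state the same formula gives rr_cn^-2 unless the risk model
    overrides it explicitly.
    """
    if state.cn == 0 and risk.null_rr is not None:
        return risk.null_rr
    return risk.rr_cn ** (state.cn - 2) * risk.rr_allele ** state.b_count


def case_state_frequencies(
    ctrl: StateDistribution, risk: RiskModel
) -> StateDistribution:
    """Case-population frequencies: P_case(g) ∝ P_ctrl(g) · RR(g)."""
    weights = [ctrl[s] * state_relative_risk(s, risk) for s in STATES]
    total = sum(weights)
    return StateDistribution([w / total for w in weights])


# ---------------------------------------------------------------------------
# Scenario grids
# ---------------------------------------------------------------------------

F_NORM_GRID = (0.8, 0.5, 1.0 / 3.0)
F_B_GRID = (0.05, 0.20, 0.35, 0.50)
RR_GRID = (1.0, 1.2, 1.5, 2.0)


def frequency_scenario_grid() -> list[ScenarioSpec]:
    """The 36 frequency scenarios: f_norm × CNV type × f(B)."""
    return [
        ScenarioSpec(f_norm, cnv_type, f_b)
        for f_norm, cnv_type, f_b in itertools.product(
            F_NORM_GRID, CNV_TYPES, F_B_GRID
        )
    ]


def risk_scenario_grid() -> list[RiskModel]:
    """The 16 risk scenarios: RR_CN × RR_allele over {1, 1.2, 1.5, 2}."""
    return [
        RiskModel(rr_cn, rr_allele)
        for rr_cn, rr_allele in itertools.product(RR_GRID, RR_GRID)
    ]


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def scenario_from_dict(d: Mapping) -> tuple[ScenarioSpec, RiskModel]:
    """Build (ScenarioSpec, RiskModel) from a config mapping.

    Recognized keys: f_norm, cnv_type, f_b, rr_cn, rr_allele (risk keys
    default to the null model).
    """
    spec = ScenarioSpec(float(d["f_norm"]), d["cnv_type"], float(d["f_b"]))
    risk = RiskModel(float(d.get("rr_cn", 1.0)), float(d.get("rr_allele", 1.0)))
    return spec, risk


def load_scenarios(path: str | Path) -> list[tuple[ScenarioSpec, RiskModel]]:
    """Read scenarios from a YAML or JSON file (a mapping or list of mappings)."""
    text = Path(path).read_text()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if isinstance(data, Mapping):
        data = [data]
    return [scenario_from_dict(d) for d in data]


def dump_scenarios(
    entries: Iterable[tuple[ScenarioSpec, RiskModel]], path: str | Path
) -> None:
    """Write scenarios to YAML or JSON (by file extension)."""
    rows = [{**spec.to_dict(), **risk.to_dict()} for spec, risk in entries]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
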