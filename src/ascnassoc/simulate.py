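"""Case-control cohort simulation over ASCN states.

The pipeline mirrors how array data degrade in practice:

1. draw control states from the analytic control frequencies and case states
   from the risk-tilted case frequencies (:func:`simulate_cohort`);
2. optionally collapse each state to a bi-allelic genotype call
   (AA/AB/BB/missing) via a per-state calling-probability table
   (:func:`degrade_to_genotypes`);
3. optionally corrupt the states themselves with CNV calling errors governed
   by a detection sensitivity and specificity (:func:`inject_errors`).

All randomness flows through numpy Generators; every public function accepts
an integer seed, a ``SeedSequence`` or a ``Generator``, so stages are
independently reproducible from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    STATES,
    STATE_INDEX,
    STATE_LABELS,
    AscnState,
    RiskModel,
    ScenarioSpec,
    StateDistribution,
    case_state_frequencies,
    control_state_frequencies,
)

#: Bi-allelic call codes used throughout (int8 in Cohort.calls).
CALL_LABELS = ("AA", "AB", "BB", "missing")
CALL_AA, CALL_AB, CALL_BB, CALL_MISSING = range(4)

_STATE_CN = np.array([s.cn for s in STATES], dtype=np.int8)
_STATE_B = np.array([s.b_count for s in STATES], dtype=np.int8)
_STATE_A = np.array([s.a_count for s in STATES], dtype=np.int8)


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Cohort:
    """A simulated case-control sample at one SNP-in-CNV locus.

    ``state_idx`` indexes into the canonical 15-state list; ``phenotype`` is
    0 for controls and 1 for cases; ``calls`` (optional) holds bi-allelic
    call codes (see :data:`CALL_LABELS`).
    """

    state_idx: np.ndarray
    phenotype: np.ndarray
    calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.state_idx = np.asarray(self.state_idx, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.state_idx.shape != self.phenotype.shape:
            raise ValueError("state_idx and phenotype lengths differ")
        if self.state_idx.size and not (
            (self.state_idx >= 0).all() & (self.state_idx < len(STATES)).all()
        ):
            raise ValueError("state_idx out of range")
        if self.calls is not None:
            self.calls = np.asarray(self.calls, dtype=np.int8)
            if self.calls.shape != self.phenotype.shape:
                raise ValueError("calls length differs from phenotype")

    # Derived per-individual quantities ------------------------------------
    @property
    def n(self) -> int:
        return int(self.phenotype.size)

    @property
    def cn(self) -> np.ndarray:
        """Total copy number per individual."""
        return _STATE_CN[self.state_idx]

    @property
    def b_count(self) -> np.ndarray:
        """B-allele count (from the ASCN state) per individual."""
        return _STATE_B[self.state_idx]

    @property
    def a_count(self) -> np.ndarray:
        return _STATE_A[self.state_idx]

    @property
    def states(self) -> list[AscnState]:
        return [STATES[i] for i in self.state_idx]

    def state_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(control_counts, case_counts), each length 15 in canonical order."""
        ctrl = np.bincount(
            self.state_idx[self.phenotype == 0], minlength=len(STATES)
        )
        case = np.bincount(
            self.state_idx[self.phenotype == 1], minlength=len(STATES)
        )
        return ctrl, case

    # Serialization ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "individual_id": [f"ind{i + 1}" for i in range(self.n)],
                "phenotype": self.phenotype.astype(int),
                "state": [STATE_LABELS[i] for i in self.state_idx],
            }
        )
        if self.calls is not None:
            df["call"] = [CALL_LABELS[c] for c in self.calls]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        state_idx = np.array(
            [STATE_INDEX[AscnState.from_label(s)] for s in df["state"]],
            dtype=np.int8,
        )
        calls = None
        if "call" in df.columns:
            lut = {lab: code for code, lab in enumerate(CALL_LABELS)}
            calls = np.array([lut[c] for c in df["call"]], dtype=np.int8)
        return cls(state_idx, df["phenotype"].to_numpy(), calls)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Cohort":
        # keep_default_na: the NULL state label must not parse as NaN
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def simulate_cohort(
    spec: ScenarioSpec,
    risk: RiskModel,
    n_cases: int,
    n_controls: int,
    seed,
) -> Cohort:
    """Draw an i.i.d. case-control cohort for one scenario and risk model.

    Controls are drawn from the analytic control state frequencies and cases
    from the risk-tilted case frequencies.  Reproducible for a fixed seed.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    rng = as_rng(seed)
    ctrl = control_state_frequencies(spec)
    case = case_state_frequencies(ctrl, risk)
    return cohort_from_counts(
        rng.multinomial(n_controls, ctrl.as_vector()),
        rng.multinomial(n_cases, case.as_vector()),
    )


def cohort_from_counts(
    control_counts: np.ndarray, case_counts: np.ndarray
) -> Cohort:
    """Assemble a Cohort from per-state control and case counts."""
    idx = np.arange(len(STATES), dtype=np.int8)
    state_idx = np.concatenate(
        [np.repeat(idx, control_counts), np.repeat(idx, case_counts)]
    )
    phenotype = np.concatenate(
        [
            np.zeros(int(np.sum(control_counts)), dtype=np.int8),
            np.ones(int(np.sum(case_counts)), dtype=np.int8),
        ]
    )
    return Cohort(state_idx, phenotype)


# ---------------------------------------------------------------------------
# Bi-allelic genotype degradation
# ---------------------------------------------------------------------------

class CallTable:
    """P(bi-allelic call | ASCN state): a 15 x 4 row-stochastic matrix.

    Rows follow the canonical state order; columns are AA, AB, BB, missing.
    """

    ROW_TOL = 1e-9

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(STATES), len(CALL_LABELS)):
            raise ValueError(
                f"call table must be {len(STATES)}x{len(CALL_LABELS)}"
            )
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("call probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=self.ROW_TOL, rtol=0):
            raise ValueError("call table rows must sum to 1")
        self.probs = probs

    def row(self, state: AscnState) -> np.ndarray:
        return self.probs[STATE_INDEX[state]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(CALL_LABELS))
        df.insert(0, "state", STATE_LABELS)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CallTable":
        # keep_default_na: the NULL state label must not parse as NaN
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        probs = np.zeros((len(STATES), len(CALL_LABELS)))
        for r in df.itertuples():
            probs[STATE_INDEX[AscnState.from_label(r.state)]] = [
                getattr(r, c) for c in CALL_LABELS
            ]
        return cls(probs)


def default_call_table() -> CallTable:
    """The package's default calling-probability table.

    A documented synthetic stand-in calibrated to the qualitative behaviour of
    SNP arrays inside CNVs: states with 1 or 2 total copies call faithfully
    (A→AA, B→BB; missing rate below 1%), while 0-, 3- and 4-copy states are
    mostly missing (≥50%) with the residual mass on compatible calls, and the
    heterozygous 3- and 4-copy states have deliberately asymmetric missing
    rates (AAB vs ABB, AAAB vs ABBB).  Shipped as package data
    (``data/call_table_default.tsv``); replace it with an empirically
    estimated table when one is available.
    """
    path = resources.files("ascnassoc").joinpath("data/call_table_default.tsv")
    with resources.as_file(path) as p:
        return CallTable.from_tsv(p)


def degrade_to_genotypes(cohort: Cohort, table: CallTable, seed) -> Cohort:
    """Collapse each individual's ASCN state to a bi-allelic call.

    Each call is an independent draw from the table row of the individual's
    state.  Phenotypes and states are untouched; returns a new Cohort with
    ``calls`` filled in.
    """
    rng = as_rng(seed)
    # inverse-CDF draw per individual against the cumulative rows
    cum = np.cumsum(table.probs, axis=1)[cohort.state_idx]
    u = rng.random(cohort.n)
    calls = (u[:, None] > cum).sum(axis=1).astype(np.int8)
    return Cohort(cohort.state_idx.copy(), cohort.phenotype.copy(), calls)


# ---------------------------------------------------------------------------
# CNV calling-error injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    """Sensitivity and specificity of CNV detection.

    A true CNV carrier (CN != 2) is detected with probability ``sensitivity``;
    a true 2-copy individual is falsely flagged as a CNV carrier with
    probability ``1 - specificity``.
    """

    sensitivity: float
    specificity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _missed_detection_target() -> np.ndarray:
    """State each CN!=2 state collapses to when its CNV goes undetected.

    Homozygous states keep their allele (AA or BB), heterozygous states
    become AB; the NULL state is marked -1 (resolved uniformly over
    {AA, AB, BB} at draw time).
    """
    target = np.full(len(STATES), -2, dtype=np.int8)
    aa, ab, bb = (
        STATE_INDEX[AscnState(2, 0)],
        STATE_INDEX[AscnState(1, 1)],
        STATE_INDEX[AscnState(0, 2)],
    )
    for i, s in enumerate(STATES):
        if s.cn == 2:
            continue
        if s.cn == 0:
            target[i] = -1
        elif s.b_count == 0:
            target[i] = aa
        elif s.a_count == 0:
            target[i] = bb
        else:
            target[i] = ab
    return target


_MISSED_TARGET = _missed_detection_target()

# false-positive remap: (true CN=2 state, wrong CN) -> equally likely states
_FALSE_POSITIVE_MAP: dict[tuple[str, int], tuple[str, ...]] = {
    ("AA", 0): ("NULL",),
    ("AA", 1): ("A",),
    ("AA", 3): ("AAA",),
    ("AA", 4): ("AAAA",),
    ("BB", 0): ("NULL",),
    ("BB", 1): ("B",),
    ("BB", 3): ("BBB",),
    ("BB", 4): ("BBBB",),
    ("AB", 0): ("NULL",),
    ("AB", 1): ("A", "B"),
    ("AB", 3): ("AAB", "ABB"),
    ("AB", 4): ("AAAB", "AABB", "ABBB"),
}
_FP_CHOICES = {
    (STATE_INDEX[AscnState.from_label(st)], cn): np.array(
        [STATE_INDEX[AscnState.from_label(t)] for t in targets], dtype=np.int8
    )
    for (st, cn), targets in _FALSE_POSITIVE_MAP.items()
}
_WRONG_CN_CHOICES = np.array([0, 1, 3, 4])


def inject_errors(cohort: Cohort, err: ErrorSpec, seed) -> Cohort:
    """Corrupt ASCN states with CNV calling errors.

    * A CN != 2 individual's CNV goes undetected with probability
      1 - sensitivity; the state then collapses to a plain genotype — AA or BB
      if homozygous, AB if heterozygous, and uniformly AA/AB/BB from NULL.
    * A CN = 2 individual is falsely flagged with probability
      1 - specificity; a wrong copy number is drawn uniformly from
      {0, 1, 3, 4} and the state is remapped compatibly with its alleles
      (AA→A/AAA/AAAA, BB→B/BBB/BBBB, AB→{A,B}, {AAB,ABB} or
      {AAAB,AABB,ABBB} with equal probabilities; wrong CN 0 → NULL).

    Phenotypes, cohort size and any existing calls are unchanged.
    """
    rng = as_rng(seed)
    state_idx = cohort.state_idx.copy()
    cn = cohort.cn
    u = rng.random(cohort.n)

    # missed detections among true CNV carriers
    missed = (cn != 2) & (u >= err.sensitivity)
    targets = _MISSED_TARGET[state_idx[missed]]
    from_null = targets == -1
    if from_null.any():
        two_copy = np.array(
            [
                STATE_INDEX[AscnState(2, 0)],
                STATE_INDEX[AscnState(1, 1)],
                STATE_INDEX[AscnState(0, 2)],
            ],
            dtype=np.int8,
        )
        targets[from_null] = rng.choice(two_copy, size=int(from_null.sum()))
    state_idx[missed] = targets

    # false positives among true 2-copy individuals
    false_pos = (cn == 2) & (u >= err.specificity)
    fp_idx = np.flatnonzero(false_pos)
    if fp_idx.size:
        wrong_cn = rng.choice(_WRONG_CN_CHOICES, size=fp_idx.size)
        for i, wcn in zip(fp_idx, wrong_cn):
            options = _FP_CHOICES[(int(state_idx[i]), int(wcn))]
            state_idx[i] = options[rng.integers(len(options))]

    calls = None if cohort.calls is None else cohort.calls.copy()
    return Cohort(state_idx, cohort.phenotype.copy(), calls)
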