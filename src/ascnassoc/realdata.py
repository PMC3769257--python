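"""Real-data analysis path: ASCN states from CNV calls plus B-allele
frequencies, SNP filtering, two-group association and multiple-testing
correction.

Inputs follow the common array-CNV toolchain: PennCNV-style ``.rawcnv``
segment calls (only CN != 2 segments are listed; everything else is two-copy),
a per-SNP/per-sample table of B-allele frequencies (BAF) and bi-allelic calls,
a SNP annotation table, and a two-group phenotype table.  Coordinates are
1-based inclusive throughout, as in PennCNV output.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import STATE_INDEX, AscnState
from .simulate import CALL_LABELS, CALL_MISSING, Cohort
from . import assoc

MAX_CN = 4


class AmbiguousCnvError(ValueError):
    """A sample has overlapping CNV calls with conflicting copy numbers."""


class RawCnvParseError(ValueError):
    """A .rawcnv line did not match the expected format."""


@dataclass(frozen=True)
class CnvCall:
    """One PennCNV segment call: a CN != 2 region in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    num_snps: int
    start_snp: str = ""
    end_snp: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.cn == 2 or not (0 <= self.cn <= MAX_CN):
            raise ValueError(f"segment copy number must be in {{0,1,3,4}}, got {self.cn}")

    def contains(self, chrom: str, position: int) -> bool:
        return self.chrom == chrom and self.start <= position <= self.end


_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?(?:\s+endsnp=(?P<endsnp>\S+))?\s*$"
)


def read_rawcnv(path: str | Path) -> list[CnvCall]:
    """Parse a PennCNV .rawcnv file into CnvCall records."""
    calls: list[CnvCall] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        m = _RAWCNV_RE.match(line.strip())
        if m is None:
            raise RawCnvParseError(f"{path}:{lineno}: unparseable line: {line!r}")
        calls.append(
            CnvCall(
                sample_id=m["sample"],
                chrom=m["chrom"],
                start=int(m["start"]),
                end=int(m["end"]),
                cn=int(m["cn"]),
                num_snps=int(m["numsnp"].replace(",", "")),
                start_snp=m["startsnp"] or "",
                end_snp=m["endsnp"] or "",
            )
        )
    return calls


def write_rawcnv(calls: list[CnvCall], path: str | Path) -> None:
    """Write CnvCall records back out in the .rawcnv dialect."""
    lines = []
    for c in calls:
        state = {0: 1, 1: 2, 3: 5, 4: 6}[c.cn]  # PennCNV HMM state labels
        line = (
            f"chr{c.chrom}:{c.start}-{c.end} numsnp={c.num_snps} "
            f"length={c.end - c.start + 1} state{state},cn={c.cn} {c.sample_id}"
        )
        if c.start_snp:
            line += f" startsnp={c.start_snp}"
        if c.end_snp:
            line += f" endsnp={c.end_snp}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def resolve_cn(
    chrom: str, position: int, sample_id: str, calls: list[CnvCall]
) -> int:
    """Total copy number of one sample at one position.

    Positions outside every listed segment are two-copy.  Overlapping calls
    for the sample with conflicting copy numbers raise AmbiguousCnvError.
    """
    hits = {
        c.cn
        for c in calls
        if c.sample_id == sample_id and c.contains(chrom, position)
    }
    if len(hits) > 1:
        raise AmbiguousCnvError(
            f"sample {sample_id} has conflicting CNV calls at "
            f"chr{chrom}:{position}: CN {sorted(hits)}"
        )
    return hits.pop() if hits else 2


def assign_ascn(cn: int, baf: float) -> AscnState:
    """Most plausible ASCN state given a resolved copy number and a BAF.

    With cn copies, a state with b B alleles has expected BAF b/cn; the
    state nearest the observed BAF is chosen (for CN=1 this reduces to the
    0.5 rule: BAF < 0.5 → A, BAF > 0.5 → B).  Ties break toward the lower
    B count.  CN=0 is always NULL.
    """
    if not (0 <= cn <= MAX_CN):
        raise ValueError(f"copy number must be in 0..{MAX_CN}, got {cn}")
    if not (0.0 <= baf <= 1.0):
        raise ValueError(f"BAF must lie in [0, 1], got {baf}")
    if cn == 0:
        return AscnState(0, 0)
    expected = np.arange(cn + 1) / cn
    b = int(np.argmin(np.abs(expected - baf)))  # argmin ties → lower b
    return AscnState(cn - b, b)


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(
    snp_stats: pd.DataFrame,
    maf_min: float = 0.05,
    abnormal_cn_min: float = 0.05,
    missing_max: float = 0.05,
) -> pd.DataFrame:
    """Apply the SNP retention rules for the within-CNV association analysis.

    Expects per-SNP columns ``snp_id``, ``maf``, ``in_cnv_region`` (bool),
    ``abnormal_cn_freq`` and ``missing_rate``.  A SNP is retained when its
    MAF is at least ``maf_min``, it lies in a CNV region, and the frequency
    of abnormal (non-2) copy numbers is at least ``abnormal_cn_min``.  The
    returned frame adds ``retained`` plus ``allele_bi_eligible`` (retained
    and missing rate below ``missing_max``).
    """
    out = snp_stats.copy()
    out["retained"] = (
        (out["maf"] >= maf_min)
        & out["in_cnv_region"].astype(bool)
        & (out["abnormal_cn_freq"] >= abnormal_cn_min)
    )
    out["allele_bi_eligible"] = out["retained"] & (
        out["missing_rate"] < missing_max
    )
    return out


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def li_ji_effective_tests(cn_matrix: np.ndarray | pd.DataFrame) -> int:
    """Effective number of independent tests from copy-number correlations.

    Eigen-decomposes the SNP × SNP correlation matrix of the per-individual
    copy numbers and counts Meff = Σ_i [ 1(λ_i ≥ 1) + (λ_i − floor(λ_i)) ],
    rounded up to an integer for use in a Bonferroni correction.  Constant
    columns carry no correlation information and are dropped with a warning.
    """
    X = np.asarray(cn_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("cn_matrix must be 2-D (individuals x SNPs)")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant copy-number columns",
            stacklevel=2,
        )
        X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need >= 2 SNPs with non-constant copy numbers")
    corr = np.corrcoef(X, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)
    eigvals = np.clip(eigvals, 0.0, None)
    meff = float(
        np.sum((eigvals >= 1.0).astype(float) + (eigvals - np.floor(eigvals)))
    )
    return max(1, math.ceil(meff - 1e-9))


def bonferroni(
    p_values: np.ndarray, m: int, alpha: float = 0.05
) -> np.ndarray:
    """Boolean significance flags at the Bonferroni-corrected level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    return p < alpha / m


# ---------------------------------------------------------------------------
# End-to-end two-group analysis
# ---------------------------------------------------------------------------

_CALL_CODE = {lab: code for code, lab in enumerate(CALL_LABELS)}
_CALL_CODE.update({"NC": CALL_MISSING, "NA": CALL_MISSING, "": CALL_MISSING})


def analyze(
    rawcnv_path: str | Path,
    snps_path: str | Path,
    baf_path: str | Path,
    pheno_path: str | Path,
    alpha: float = 0.05,
    maf_min: float = 0.05,
    abnormal_cn_min: float = 0.05,
    missing_max: float = 0.05,
) -> pd.DataFrame:
    """Run the within-CNV association analysis between two groups.

    Steps: resolve each (SNP, sample) copy number from the CNV calls, assign
    the ASCN state from the BAF, filter SNPs (MAF, CNV membership, abnormal-CN
    frequency), run the four ASCN strategies plus the bi-allelic strategy on
    eligible SNPs with group 1 as cases and group 2 as controls, and apply
    Bonferroni corrections with each strategy's own test count — the
    copy-number trend strategy uses the Li-Ji effective test count computed
    from the copy-number correlation matrix.

    Returns one row per retained SNP with the per-strategy p-values, joint
    odds-ratio estimates and corrected significance flags.
    """
    calls = read_rawcnv(rawcnv_path)
    snps = pd.read_csv(snps_path, sep="\t", dtype={"chrom": str})
    baf = pd.read_csv(baf_path, sep="\t", dtype={"sample_id": str})
    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"sample_id": str})

    groups = set(pheno["group"].astype(int))
    if groups != {1, 2}:
        raise ValueError(f"phenotype groups must be coded 1 and 2, got {sorted(groups)}")
    phenotype_of = {
        r.sample_id: 1 if int(r.group) == 1 else 0 for r in pheno.itertuples()
    }
    samples = list(pheno["sample_id"])

    snp_pos = {r.snp_id: (str(r.chrom), int(r.position)) for r in snps.itertuples()}
    baf = baf[baf["sample_id"].isin(phenotype_of)]

    # resolve (SNP, sample) copy number and ASCN state
    per_snp: dict[str, dict[str, tuple[int, AscnState, int]]] = {}
    for r in baf.itertuples():
        chrom, pos = snp_pos[r.snp_id]
        cn = resolve_cn(chrom, pos, r.sample_id, calls)
        state = assign_ascn(cn, float(r.baf))
        call_code = _CALL_CODE[str(r.call).strip()]
        per_snp.setdefault(r.snp_id, {})[r.sample_id] = (cn, state, call_code)

    # per-SNP statistics for filtering
    stat_rows = []
    for snp_id, obs in per_snp.items():
        cns = np.array([obs[s][0] for s in samples if s in obs])
        codes = np.array([obs[s][2] for s in samples if s in obs])
        non_missing = codes[codes != CALL_MISSING]
        if non_missing.size:
            f_b = non_missing.mean() / 2.0  # call code equals its B count
            maf = min(f_b, 1.0 - f_b)
        else:
            maf = 0.0
        stat_rows.append(
            {
                "snp_id": snp_id,
                "maf": maf,
                "in_cnv_region": bool((cns != 2).any()),
                "abnormal_cn_freq": float((cns != 2).mean()),
                "missing_rate": float((codes == CALL_MISSING).mean()),
            }
        )
    stats = filter_snps(
        pd.DataFrame(stat_rows), maf_min, abnormal_cn_min, missing_max
    )
    retained = stats[stats["retained"]]
    if retained.empty:
        return pd.DataFrame()

    # association per retained SNP
    rows = []
    cn_vectors = {}
    for r in retained.itertuples():
        obs = per_snp[r.snp_id]
        present = [s for s in samples if s in obs]
        state_idx = np.array([STATE_INDEX[obs[s][1]] for s in present], dtype=np.int8)
        phen = np.array([phenotype_of[s] for s in present], dtype=np.int8)
        call_codes = np.array([obs[s][2] for s in present], dtype=np.int8)
        cohort = Cohort(state_idx, phen, call_codes)
        cn_vectors[r.snp_id] = cohort.cn.astype(float)
        row = {
            "snp_id": r.snp_id,
            "n_cases": int((phen == 1).sum()),
            "n_controls": int((phen == 0).sum()),
        }
        for name, fit_fn in (
            ("joint", assoc.fit_joint),
            ("cn", assoc.fit_cn),
            ("allele_multi", assoc.fit_allele_multi),
            ("codominant", assoc.fit_codominant),
        ):
            try:
                fit = fit_fn(cohort)
                row[f"p_{name}"] = fit.p_value
                if name == "joint":
                    row["or_cn"] = fit.or_cn
                    row["or_allele"] = fit.or_allele
            except ValueError:
                row[f"p_{name}"] = np.nan
        if bool(r.allele_bi_eligible):
            try:
                row["p_allele_bi"] = assoc.fit_allele_bi(cohort).p_value
            except ValueError:
                row["p_allele_bi"] = np.nan
        else:
            row["p_allele_bi"] = np.nan
        rows.append(row)
    results = pd.DataFrame(rows)

    # multiple-testing corrections, per strategy test count
    m_ascn = len(results)
    m_bi = int(results["p_allele_bi"].notna().sum())
    cn_matrix = np.column_stack([cn_vectors[s] for s in results["snp_id"]])
    try:
        m_cn = li_ji_effective_tests(cn_matrix)
    except ValueError:
        m_cn = m_ascn
    results["m_cn_effective"] = m_cn
    for name, m in (
        ("joint", m_ascn),
        ("allele_multi", m_ascn),
        ("codominant", m_ascn),
        ("cn", m_cn),
        ("allele_bi", max(m_bi, 1)),
    ):
        p = results[f"p_{name}"].to_numpy(dtype=float)
        sig = np.zeros(len(results), dtype=bool)
        ok = ~np.isnan(p)
        sig[ok] = bonferroni(p[ok], m, alpha)
        results[f"sig_{name}"] = sig
    return results
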