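"""TPM normalization, knockdown quantification and a count simulator.

Knockdown of the targeted transcript is quantified on the TPM scale as
(experimental arm mean) / (control arm mean) x 100, with a two-sided
Student's t-test (pooled variance; Welch optional) over per-replicate
target TPM. Differential-expression calling itself is not performed here:
the misexpression summary consumes per-transcript significance flags from
an external pipeline or the simulator.

``simulate_counts`` draws negative-binomial counts around log-normal
baseline means, scales the target transcript by the knockdown factor in
the experimental arm, and optionally perturbs a seeded fraction of
non-target transcripts as a stand-in for collateral activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import read_table, write_table

EXPERIMENTAL = "experimental"
CONTROL = "control"


@dataclass(frozen=True)
class CountMatrix:
    """Raw transcript counts with effective lengths and sample group labels.

    ``counts`` is transcripts x samples; ``lengths`` (nt) indexes transcripts;
    ``groups`` maps each sample to 'experimental' or 'control'.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths must share the transcript index")
        if set(self.counts.columns) != set(self.groups.index):
            raise ValueError("groups must label exactly the count matrix samples")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be > 0")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not set(self.groups) <= {EXPERIMENTAL, CONTROL}:
            raise ValueError(f"group labels must be {EXPERIMENTAL!r} or {CONTROL!r}")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def to_tsv(self, counts_path: str | Path, groups_path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "length", self.lengths)
        df.insert(0, "transcript_id", df.index)
        write_table(df, counts_path)
        gdf = pd.DataFrame({"sample": self.groups.index, "group": self.groups.values})
        write_table(gdf, groups_path)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, groups_path: str | Path) -> "CountMatrix":
        df = read_table(counts_path, required=["transcript_id", "length"])
        df = df.set_index("transcript_id")
        lengths = df.pop("length")
        gdf = read_table(groups_path, required=["sample", "group"])
        groups = pd.Series(gdf["group"].values, index=gdf["sample"].values)
        return cls(counts=df, lengths=lengths, groups=groups)


def tpm(matrix: CountMatrix | pd.DataFrame, lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts-per-million normalization; each sample column sums to 1e6.

    rate_i = count_i / length_i; TPM_i = rate_i / sum(rate) * 1e6.
    All-zero samples are an error (the scale factor is undefined).
    """
    if isinstance(matrix, CountMatrix):
        counts, lengths = matrix.counts, matrix.lengths
    else:
        if lengths is None:
            raise ValueError("lengths required when passing a bare counts frame")
        counts = matrix
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


@dataclass(frozen=True)
class KnockdownResult:
    percent: float            # experimental mean / control mean x 100
    t_statistic: float
    p_value: float
    experimental_mean: float
    control_mean: float


def knockdown_percent(
    tpm_matrix: pd.DataFrame,
    target_id: str,
    groups: pd.Series | Mapping[str, str],
    equal_var: bool = True,
) -> KnockdownResult:
    """Residual target expression (%) with a two-sample t-test.

    ``equal_var=True`` is the classical pooled-variance Student's t-test;
    set False for Welch. Arms with identical constant values give t = 0,
    p = 1 (and p = 0 for distinct constants), since the test statistic is
    otherwise undefined.
    """
    if target_id not in tpm_matrix.index:
        raise KeyError(f"target transcript {target_id!r} not in matrix")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    exp_samples = [s for s in tpm_matrix.columns if groups.get(s) == EXPERIMENTAL]
    ctl_samples = [s for s in tpm_matrix.columns if groups.get(s) == CONTROL]
    if len(exp_samples) < 2 or len(ctl_samples) < 2:
        raise ValueError("need >= 2 replicates per arm for the t-test")
    x = tpm_matrix.loc[target_id, exp_samples].to_numpy(dtype=float)
    y = tpm_matrix.loc[target_id, ctl_samples].to_numpy(dtype=float)
    if y.mean() == 0:
        raise ValueError("control arm mean is zero; knockdown percent undefined")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        t_stat, p = (0.0, 1.0) if x[0] == y[0] else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return KnockdownResult(
        percent=100.0 * x.mean() / y.mean(),
        t_statistic=float(t_stat),
        p_value=float(p),
        experimental_mean=float(x.mean()),
        control_mean=float(y.mean()),
    )


def misexpressed_fraction(
    flags: pd.Series | Sequence[bool],
    total: int,
    target_id: str | None = None,
) -> float:
    """Percent of all assayed transcripts flagged as misexpressed.

    ``flags`` are per-transcript significance booleans from an external
    differential-expression pipeline; the intended target (if named and
    present in the flag index) is excluded from the numerator.
    """
    flags = pd.Series(flags)
    if target_id is not None and target_id in flags.index:
        flags = flags.drop(target_id)
    n_flagged = int(flags.sum())
    if total <= 0:
        raise ValueError("total transcript count must be > 0")
    if n_flagged > total:
        raise ValueError("flagged count exceeds the stated total")
    return 100.0 * n_flagged / total


def simulate_counts(
    seed: int,
    n_transcripts: int = 1000,
    n_reps: int = 3,
    knockdown_target: str = "target_gene",
    knockdown_factor: float = 0.02,
    offtarget_fraction: float = 0.01,
    dispersion: float = 0.1,
    baseline_mean_log: float = float(np.log(100.0)),
    baseline_sigma_log: float = 1.2,
    target_mean: float = 2000.0,
    offtarget_sigma_log: float = 0.5,
    length_range: tuple[int, int] = (500, 3000),
) -> CountMatrix:
    """Seeded negative-binomial count matrix with a planted knockdown.

    Baseline means are log-normal across transcripts; the target transcript
    gets a fixed high baseline (``target_mean``), reflecting that targets
    are assayed at developmental stages of peak expression. In the
    experimental arm the target mean is multiplied by ``knockdown_factor``
    and a seeded ``offtarget_fraction`` of non-targets is perturbed by
    symmetric log-normal fold changes (a collateral-activity stand-in).
    Counts are NB with common dispersion (variance mu + dispersion*mu^2).
    Identical seeds give identical matrices.
    """
    if n_transcripts < 2 or n_reps < 1:
        raise ValueError("need >= 2 transcripts and >= 1 replicate")
    if not 0 < knockdown_factor <= 1:
        raise ValueError("knockdown_factor must be in (0, 1]")
    if not 0 <= offtarget_fraction < 1:
        raise ValueError("offtarget_fraction must be in [0, 1)")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    ids = [f"tx{i:05d}" for i in range(1, n_transcripts)] + [knockdown_target]
    base_mu = rng.lognormal(baseline_mean_log, baseline_sigma_log, size=n_transcripts)
    base_mu[-1] = target_mean
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_transcripts)

    exp_mu = base_mu.copy()
    exp_mu[-1] *= knockdown_factor
    n_off = int(round(offtarget_fraction * (n_transcripts - 1)))
    if n_off:
        off_idx = rng.choice(n_transcripts - 1, size=n_off, replace=False)
        exp_mu[off_idx] *= rng.lognormal(0.0, offtarget_sigma_log, size=n_off)

    r = 1.0 / dispersion
    def draw(mu: np.ndarray, k: int) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(len(mu), k))

    ctl = draw(base_mu, n_reps)
    exp = draw(exp_mu, n_reps)
    samples = [f"ctl_{i + 1}" for i in range(n_reps)] + [f"exp_{i + 1}" for i in range(n_reps)]
    counts = pd.DataFrame(
        np.hstack([ctl, exp]), index=pd.Index(ids, name="transcript_id"), columns=samples
    )
    groups = pd.Series(
        [CONTROL] * n_reps + [EXPERIMENTAL] * n_reps, index=samples, name="group"
    )
    return CountMatrix(counts=counts, lengths=pd.Series(lengths, index=counts.index), groups=groups)
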