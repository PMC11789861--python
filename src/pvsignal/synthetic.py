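"""Synthetic spontaneous-report corpora with known injected signals.

The generator emulates a FAERS-style extract: each report names one
primary-suspect drug (plus a Poisson number of co-reported drugs), carries
at least one reaction PT, and has demographic fields with heavy
missingness.  One designated *target drug* occurs with configurable
prevalence; conditional on drug status, PTs are independent Bernoulli
draws, with selected PTs reported at ``rate_ratio`` times their background
rate on target-drug reports.  Because the injected pairs and ratios are
returned as ground truth, every downstream stage (contingency counting,
ROR/BCPNN, dual-criterion signal detection) can be validated for recovery
of known disproportionality.

All randomness fans out from a single root seed through
``numpy.random.SeedSequence`` streams, so identical configs give
byte-identical corpora.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError
from .ingest import write_reports
from .records import DrugMention, DrugRole, ReactionMention, ReportRecord

#: Demographic category frequencies typical of oncology spontaneous
#: reports: ~75% of sex/age fields missing; countries dominated by a
#: large unclassified bucket.
DEFAULT_SEX_DIST = {"male": 0.1190, "female": 0.1295, "unknown": 0.7515}
DEFAULT_AGE_DIST = {"18-49": 0.0014, "50-69": 0.0704, ">=70": 0.1754, "unknown": 0.7528}
DEFAULT_COUNTRY_DIST = {"US": 0.0981, "JP": 0.0218, "DE": 0.0286, "FR": 0.0286, "XX": 0.8229}

AGE_BAND_RANGES = {"18-49": (18.0, 49.0), "50-69": (50.0, 69.0), ">=70": (70.0, 90.0)}

DEFAULT_WINDOW = (_dt.date(2020, 6, 1), _dt.date(2023, 6, 1))


def _check_dist(name: str, dist: dict) -> None:
    probs = np.asarray(list(dist.values()), dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ConfigError(f"{name} probabilities must lie in [0, 1]")
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ConfigError(f"{name} probabilities must sum to 1 (got {probs.sum():.4f})")


@dataclass
class SyntheticConfig:
    """Generative-model parameters for one synthetic corpus.

    ``background_pt_rates`` is the per-PT Bernoulli reporting probability
    on non-target reports; when ``None`` a vector is drawn once (uniform
    on [0.001, 0.05], seeded), giving about 2.5 PTs per report.
    ``injected_pairs`` lists ``(pt_index, rate_ratio)`` with ratio >= 1;
    on target-drug reports those PTs fire at ``min(1, ratio * background)``.
    """

    n_reports: int = 50_000
    n_drugs: int = 50
    n_pts: int = 100
    n_socs: int = 18
    target_drug: str = "capmatinib"
    target_drug_prevalence: float = 0.02
    background_pt_rates: Optional[np.ndarray] = None
    injected_pairs: tuple[tuple[int, float], ...] = ()
    sex_dist: dict = field(default_factory=lambda: dict(DEFAULT_SEX_DIST))
    age_dist: dict = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    country_dist: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_DIST))
    window: tuple[_dt.date, _dt.date] = DEFAULT_WINDOW
    duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be >= 0")
        for name in ("n_drugs", "n_pts", "n_socs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_socs > self.n_pts:
            raise ConfigError("n_socs cannot exceed n_pts")
        if not 0.0 <= self.target_drug_prevalence <= 1.0:
            raise ConfigError("target_drug_prevalence must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ConfigError("duplicate_rate must lie in [0, 1]")
        if self.background_pt_rates is not None:
            rates = np.asarray(self.background_pt_rates, dtype=float)
            if rates.shape != (self.n_pts,):
                raise ConfigError("background_pt_rates must have length n_pts")
            if (rates < 0).any() or (rates > 1).any():
                raise ConfigError("background_pt_rates must lie in [0, 1]")
        for pt_index, ratio in self.injected_pairs:
            if not 0 <= pt_index < self.n_pts:
                raise ConfigError(f"injected pt_index {pt_index} out of range")
            if ratio < 1.0:
                raise ConfigError(f"rate_ratio must be >= 1, got {ratio}")
        _check_dist("sex_dist", self.sex_dist)
        _check_dist("age_dist", self.age_dist)
        _check_dist("country_dist", self.country_dist)
        if self.window[0] > self.window[1]:
            raise ConfigError("window start must not be after window end")


def pt_name(index: int) -> str:
    return f"pt{index + 1:04d}"


def soc_name(index: int) -> str:
    return f"soc{index + 1:02d}"


def generate_pt_soc_map(n_pts: int, n_socs: int, seed: int = 0) -> dict[str, str]:
    """Random many-to-one PT -> SOC assignment in which every SOC receives
    at least one PT (the first ``n_socs`` PTs pin one SOC each)."""
    if n_socs > n_pts:
        raise ConfigError(f"n_socs ({n_socs}) cannot exceed n_pts ({n_pts})")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    assignment = np.concatenate(
        [np.arange(n_socs), rng.integers(0, n_socs, size=n_pts - n_socs)]
    )
    return {pt_name(i): soc_name(int(assignment[i])) for i in range(n_pts)}


def _categorical(rng, categories: list, probs: np.ndarray, size: int) -> np.ndarray:
    idx = rng.choice(len(categories), size=size, p=probs / probs.sum())
    return idx


def generate_reports(
    config: SyntheticConfig,
) -> tuple[list[ReportRecord], dict]:
    """Generate a deduplicated corpus plus its ground-truth sidecar.

    Returns ``(reports, ground_truth)`` where ``ground_truth`` records the
    target drug, the effective background rates and every injected
    ``(pt_name, rate_ratio)`` pair.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_rates, ss_struct, ss_pts, ss_demo, ss_dates = root.spawn(5)

    if config.background_pt_rates is None:
        rates = np.random.default_rng(ss_rates).uniform(0.001, 0.05, size=config.n_pts)
    else:
        rates = np.asarray(config.background_pt_rates, dtype=float).copy()

    target_rates = rates.copy()
    for pt_index, ratio in config.injected_pairs:
        target_rates[pt_index] = min(1.0, ratio * rates[pt_index])

    n = config.n_reports
    rng_struct = np.random.default_rng(ss_struct)
    rng_pts = np.random.default_rng(ss_pts)
    rng_demo = np.random.default_rng(ss_demo)
    rng_dates = np.random.default_rng(ss_dates)

    is_target = rng_struct.random(n) < config.target_drug_prevalence

    # PT incidence matrix: independent Bernoulli per (report, PT); a report
    # whose draws all miss gets one PT sampled proportional to its rates,
    # so every report carries >= 1 reaction.
    u = rng_pts.random((n, config.n_pts))
    row_rates = np.where(is_target[:, None], target_rates[None, :], rates[None, :])
    mat = u < row_rates
    del u
    empty = ~mat.any(axis=1)
    if empty.any():
        for i in np.flatnonzero(empty):
            p = row_rates[i]
            mat[i, rng_pts.choice(config.n_pts, p=p / p.sum())] = True
    del row_rates

    # co-reported drugs: one primary suspect per report (the target drug on
    # target reports, a random other drug elsewhere) plus Poisson(1) extras
    # with non-suspect roles
    other_drugs = [f"drug{j + 1:03d}" for j in range(config.n_drugs)]
    extra_roles = (DrugRole.SECONDARY_SUSPECT, DrugRole.CONCOMITANT, DrugRole.INTERACTING)
    n_extra = rng_struct.poisson(1.0, size=n)
    ps_choice = rng_struct.integers(0, config.n_drugs, size=n)

    # demographics
    sex_cats = list(config.sex_dist)
    sex_idx = _categorical(rng_demo, sex_cats, np.array(list(config.sex_dist.values())), n)
    age_cats = list(config.age_dist)
    age_idx = _categorical(rng_demo, age_cats, np.array(list(config.age_dist.values())), n)
    age_u = rng_demo.random(n)
    country_cats = list(config.country_dist)
    country_idx = _categorical(
        rng_demo, country_cats, np.array(list(config.country_dist.values())), n
    )
    start_ord, end_ord = config.window[0].toordinal(), config.window[1].toordinal()
    date_ords = rng_dates.integers(start_ord, end_ord + 1, size=n)

    rows, cols = np.nonzero(mat)
    boundaries = np.searchsorted(rows, np.arange(n + 1))

    reports: list[ReportRecord] = []
    for i in range(n):
        pts = tuple(
            ReactionMention(pt_name(int(j))) for j in cols[boundaries[i] : boundaries[i + 1]]
        )
        if is_target[i]:
            drugs = [DrugMention(config.target_drug, DrugRole.PRIMARY_SUSPECT)]
        else:
            drugs = [DrugMention(other_drugs[ps_choice[i]], DrugRole.PRIMARY_SUSPECT)]
        k = int(n_extra[i])
        if k:
            extra_idx = rng_struct.integers(0, config.n_drugs, size=k)
            role_idx = rng_struct.integers(0, len(extra_roles), size=k)
            for j, r in zip(extra_idx, role_idx):
                dm = DrugMention(other_drugs[int(j)], extra_roles[int(r)])
                if dm not in drugs:
                    drugs.append(dm)
        sex = sex_cats[sex_idx[i]]
        band = age_cats[age_idx[i]]
        if band == "unknown":
            age = None
        else:
            lo, hi = AGE_BAND_RANGES[band]
            age = round(lo + (hi - lo) * age_u[i], 1)
        country = country_cats[country_idx[i]]
        reports.append(
            ReportRecord(
                case_id=f"case{i + 1:07d}",
                version=1,
                receipt_date=_dt.date.fromordinal(int(date_ords[i])),
                sex=sex if sex in ("male", "female") else "unknown",
                age_years=age,
                country=country,
                drugs=tuple(drugs),
                reactions=pts,
            )
        )

    ground_truth = {
        "target_drug": config.target_drug,
        "n_reports": n,
        "target_drug_prevalence": config.target_drug_prevalence,
        "seed": config.seed,
        "background_pt_rates": {pt_name(i): float(r) for i, r in enumerate(rates)},
        "injected": [
            {
                "pt_name": pt_name(i),
                "pt_index": int(i),
                "rate_ratio": float(ratio),
                "background_rate": float(rates[i]),
            }
            for i, ratio in config.injected_pairs
        ],
    }
    return reports, ground_truth


def inject_duplicates(
    reports: Sequence[ReportRecord], duplicate_rate: float, seed: int = 0
) -> list[ReportRecord]:
    """Give a fraction ``duplicate_rate`` of cases one extra record with the
    same case id and version + 1 (exercises case-version deduplication).
    """
    if not 0.0 <= duplicate_rate <= 1.0:
        raise ConfigError("duplicate_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n = len(reports)
    n_dup = int(round(duplicate_rate * n))
    picked = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    out = list(reports)
    for i in sorted(int(j) for j in picked):
        orig = reports[i]
        out.append(
            ReportRecord(
                case_id=orig.case_id,
                version=orig.version + 1,
                receipt_date=orig.receipt_date,
                sex=orig.sex,
                age_years=orig.age_years,
                country=orig.country,
                drugs=orig.drugs,
                reactions=orig.reactions,
            )
        )
    return out


def write_corpus(
    reports: Sequence[ReportRecord],
    ground_truth: dict,
    corpus_path: str | Path,
    ground_truth_path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    """Write the corpus in the pipeline's own delimited format plus the
    JSON ground-truth sidecar."""
    write_reports(reports, corpus_path, delimiter=delimiter)
    Path(ground_truth_path).write_text(json.dumps(ground_truth, indent=2) + "\n")
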