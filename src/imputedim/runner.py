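"""Full factorial study: generate -> mask -> gate -> impute -> score.

One complete matrix is generated per study; each missing rate receives an
independent MCAR mask of that same matrix. Rates failing Little's MCAR test
at the gate level are dropped. Each retained (method, rate) cell is imputed,
rounded, and scored with the fidelity profile and the unidimensionality
battery. Grand means over rates are unweighted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fidelity as fid
from . import grm, indices, missingness
from .core import IncompleteMatrix, ItemBank, ResponseMatrix, logger
from .imputers import ImputationResult, cim_impute, em_fit, em_impute, mi_impute
from .indices import IndexBattery

#: the study's nominal missing rates: 1-15% by 1, then 20-50% by 5
DEFAULT_RATES = tuple(r / 100 for r in list(range(1, 16)) + list(range(20, 51, 5)))


@dataclass
class StudyConfig:
    n: int = 5000
    k: int = 50
    a_mean: float = 1.8
    a_sd: float = 0.5
    scale: float = grm.DEFAULT_SCALE
    threshold_scheme: str = "sorted"
    difficulty_sd: float = grm.DEFAULT_DIFFICULTY_SD
    threshold_offsets: tuple[float, ...] = grm.DEFAULT_OFFSETS
    rates: tuple[float, ...] = DEFAULT_RATES
    methods: tuple[str, ...] = ("CIM", "EM", "MI")
    m: int = 100
    mi_iterations: int = 1000
    mi_burn_in: int = 200
    em_max_iter: int = 1000
    em_tol: float = 1e-6
    gate_alpha: float = 0.05
    run_gate: bool = True
    mi_pooled_indices: bool = False
    force_one_component: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        if any(not 0 < r < 1 for r in rates):
            raise ValueError("rates must lie in (0, 1)")
        if list(rates) != sorted(set(rates)):
            raise ValueError("rates must be strictly increasing")
        self.rates = rates
        self.threshold_offsets = tuple(float(v) for v in self.threshold_offsets)
        self.methods = tuple(str(m).upper() for m in self.methods)
        unknown = set(self.methods) - {"CIM", "EM", "MI"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            key: list(value) if isinstance(value, tuple) else value
            for key, value in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class StudyReport:
    config: StudyConfig
    bank: ItemBank
    complete: ResponseMatrix
    gate_table: pd.DataFrame
    retained_rates: list[float]
    fidelity_table: pd.DataFrame
    alpha_table: pd.DataFrame
    eigen_table: pd.DataFrame
    variance_table: pd.DataFrame
    citc_table: pd.DataFrame
    communalities_table: pd.DataFrame
    batteries: dict[tuple[str, float], IndexBattery]
    complete_battery: IndexBattery
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.complete.to_csv(out / "complete_matrix.csv")
        self.bank.to_csv(out / "item_bank.csv")
        self.gate_table.to_csv(out / "table1_mcar.tsv", sep="\t", index=False)
        self.fidelity_table.to_csv(out / "table2_fidelity.tsv", sep="\t", index=False)
        self.alpha_table.to_csv(out / "table3_alpha.tsv", sep="\t")
        self.eigen_table.to_csv(out / "table4_eigen.tsv", sep="\t", index=False)
        self.variance_table.to_csv(out / "table5_variance.tsv", sep="\t", index=False)
        self.citc_table.to_csv(out / "appendix1_citc.tsv", sep="\t", index=False)
        eig3 = self.eigen_table[["method", "rate", "lambda1", "lambda2", "lambda3"]]
        eig3.to_csv(out / "appendix2_eigenvalues.tsv", sep="\t", index=False)
        self.communalities_table.to_csv(
            out / "appendix3_communalities.tsv", sep="\t", index=False
        )
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def _impute_cell(
    method: str,
    inc: IncompleteMatrix,
    params,
    config: StudyConfig,
    rate_seed: int,
) -> ImputationResult:
    if method == "CIM":
        return cim_impute(inc)
    if method == "EM":
        return em_impute(inc, params=params)
    return mi_impute(
        inc,
        m=config.m,
        iterations=config.mi_iterations,
        burn_in=config.mi_burn_in,
        seed=rate_seed,
        start=params,
    )


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline for one seed and return all report tables."""
    t0 = time.time()
    bank = grm.sample_item_bank(
        config.k,
        config.n,
        a_mean=config.a_mean,
        a_sd=config.a_sd,
        seed=config.seed,
        threshold_scheme=config.threshold_scheme,
        difficulty_sd=config.difficulty_sd,
        threshold_offsets=config.threshold_offsets,
    )
    complete = grm.generate_responses(bank, seed=config.seed, scale=config.scale)
    complete_battery = indices.battery_for(
        complete, force_one_component=config.force_one_component
    )

    gate_rows = []
    gate_results = {}
    incs: dict[float, IncompleteMatrix] = {}
    em_params = {}
    need_em = config.run_gate or {"EM", "MI"} & set(config.methods)
    for i, rate in enumerate(config.rates):
        rate_seed = config.seed * 100_000 + i
        inc = missingness.apply_mcar(complete, rate, seed=rate_seed)
        incs[rate] = inc
        params = None
        if need_em:
            params = em_fit(inc, max_iter=config.em_max_iter, tol=config.em_tol)
            em_params[rate] = params
        if config.run_gate:
            res = missingness.little_mcar_test(inc, params=params)
            gate_results[rate] = res
            gate_rows.append(
                {
                    "rate": rate,
                    "chi2": res.chi2,
                    "df": res.df,
                    "sig": res.p_value,
                    "status": "" if res.p_value > config.gate_alpha else "deleted",
                }
            )

    if config.run_gate:
        retained = missingness.mcar_gate(gate_results, config.gate_alpha)
    else:
        retained = list(config.rates)
    gate_table = pd.DataFrame(
        gate_rows, columns=["rate", "chi2", "df", "sig", "status"]
    )

    fid_rows = []
    batteries: dict[tuple[str, float], IndexBattery] = {}
    for i, rate in enumerate(config.rates):
        if rate not in retained:
            continue
        inc = incs[rate]
        rate_seed = config.seed * 100_000 + i
        for method in config.methods:
            try:
                result = _impute_cell(
                    method, inc, em_params.get(rate), config, rate_seed
                )
                row = fid.distortion_profile(complete, result)
                row["rate"] = rate
                row["observed_rate"] = inc.observed_rate
                fid_rows.append(row)
                if method == "MI" and config.mi_pooled_indices:
                    batteries[(method, rate)] = _pooled_battery(result, config)
                else:
                    batteries[(method, rate)] = indices.battery_for(
                        result.completed,
                        force_one_component=config.force_one_component,
                    )
            except Exception:  # a failed cell is reported missing, not fatal
                logger.exception("cell (%s, %.0f%%) failed", method, 100 * rate)

    fidelity_table = pd.DataFrame(fid_rows).reset_index(drop=True)
    report = StudyReport(
        config=config,
        bank=bank,
        complete=complete,
        gate_table=gate_table,
        retained_rates=retained,
        fidelity_table=fidelity_table,
        alpha_table=_alpha_table(batteries, complete_battery, config),
        eigen_table=_eigen_table(batteries, complete_battery, config),
        variance_table=_variance_table(batteries, complete_battery, config),
        citc_table=_citc_table(batteries, complete_battery, config),
        communalities_table=_communalities_table(batteries, complete_battery, config),
        batteries=batteries,
        complete_battery=complete_battery,
        metadata={
            "seed": config.seed,
            "n": config.n,
            "k": config.k,
            "retained_rates": retained,
            "em_iterations": {
                str(r): p.n_iter for r, p in em_params.items()
            },
            "runtime_s": round(time.time() - t0, 2),
        },
    )
    report.metadata["runtime_s"] = round(time.time() - t0, 2)
    return report


def _pooled_battery(result: ImputationResult, config: StudyConfig) -> IndexBattery:
    """Rubin-style pooling: index battery averaged over the m MI datasets."""
    bats = [
        indices.battery_for(d, force_one_component=config.force_one_component)
        for d in result.m_datasets
    ]
    ref = bats[0]
    nr = int(round(np.mean([b.n_retained for b in bats])))
    width = max(len(b.cum_variance) for b in bats)

    def mean_padded(arrs):
        out = np.full((len(arrs), width), np.nan)
        for i, a in enumerate(arrs):
            out[i, : len(a)] = a
        return np.nanmean(out, axis=0)

    return IndexBattery(
        alpha=float(np.mean([b.alpha for b in bats])),
        citc=np.mean([b.citc for b in bats], axis=0),
        eigenvalues=np.mean([b.eigenvalues for b in bats], axis=0),
        ratio_12=float(np.mean([b.ratio_12 for b in bats])),
        gap_ratio=float(np.nanmean([b.gap_ratio for b in bats])),
        cum_variance=mean_padded([b.cum_variance for b in bats]),
        communalities=np.mean([b.communalities for b in bats], axis=0),
        n_retained=nr,
        all_eigenvalues=np.mean([b.all_eigenvalues for b in bats], axis=0),
    )


def _cells(batteries, complete_battery, config):
    yield ("complete", 0.0, complete_battery)
    for method in config.methods:
        for rate in config.rates:
            bat = batteries.get((method, rate))
            if bat is not None:
                yield (method, rate, bat)


def _alpha_table(batteries, complete_battery, config) -> pd.DataFrame:
    rows = [
        {"method": m, "rate": r, "alpha": b.alpha}
        for m, r, b in _cells(batteries, complete_battery, config)
    ]
    df = pd.DataFrame(rows)
    table = df[df.method != "complete"].pivot(
        index="rate", columns="method", values="alpha"
    )
    table.loc["MEAN"] = table.mean()
    table.attrs["complete_alpha"] = complete_battery.alpha
    return table


def _eigen_table(batteries, complete_battery, config) -> pd.DataFrame:
    rows = []
    for m, r, b in _cells(batteries, complete_battery, config):
        rows.append(
            {
                "method": m,
                "rate": r,
                "lambda1": b.eigenvalues[0],
                "lambda2": b.eigenvalues[1],
                "lambda3": b.eigenvalues[2],
                "ratio_12": b.ratio_12,
                "gap_ratio": b.gap_ratio,
            }
        )
    return pd.DataFrame(rows)


def _variance_table(batteries, complete_battery, config) -> pd.DataFrame:
    rows = []
    for m, r, b in _cells(batteries, complete_battery, config):
        row = {"method": m, "rate": r, "n_retained": b.n_retained}
        for c, v in enumerate(b.cum_variance):
            row[f"cum_var_{c + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _citc_table(batteries, complete_battery, config) -> pd.DataFrame:
    rows = []
    for m, r, b in _cells(batteries, complete_battery, config):
        row = {"method": m, "rate": r, "citc_mean": b.citc_mean}
        for j, v in enumerate(b.citc):
            row[f"item{j + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _communalities_table(batteries, complete_battery, config) -> pd.DataFrame:
    rows = []
    for m, r, b in _cells(batteries, complete_battery, config):
        row = {
            "method": m,
            "rate": r,
            "mean_communality": float(np.mean(b.communalities)),
        }
        for j, v in enumerate(b.communalities):
            row[f"item{j + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
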