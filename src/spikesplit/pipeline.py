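"""Orchestration of the two analysis tracks and their report tables.

Track 1 (qualitative / hybridological): observed phenotype class counts per
trait are screened against a battery of Mendelian ratios; the report mirrors
a classical segregation table (trait x ratio: chi2, df, p, rejected flag).

Track 2 (quantitative / mixture): each quantitative trait, per projection, is
split into two putative genotype groups by a two-component Gaussian mixture;
the group counts are chi-square-tested against 3:1 (by default) and reported
with columns mean1, var1, mean2, var2, num1, num2, numratio_1vs2, chisq,
chisq_p.  A trait is flagged as consistently segregating only when the ratio
holds in all four spike projections.

All table output is deterministic: re-running with the same config and seed
reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genetics import RatioLibrary
from .io import write_counts_csv, write_mask_pair, write_trait_table
from .mixture import em_fit, mixture_to_segregation
from .morphometry import build_trait_table
from .segregation import (
    ChiSquareResult,
    SegregationCounts,
    pearson_chi2,
    projection_consistency,
    ratio_battery,
)
from .synthetic import (
    PopulationSpec,
    SyntheticSpikeSpec,
    default_population_spec,
    render_spike,
    simulate_f2,
    simulate_traits,
)

__all__ = ["AnalysisConfig", "run_qualitative", "run_quantitative", "run_end_to_end"]

logger = logging.getLogger(__name__)

S3_COLUMNS = [
    "trait",
    "projection",
    "mean1",
    "var1",
    "mean2",
    "var2",
    "num1",
    "num2",
    "numratio_1vs2",
    "chisq",
    "chisq_p",
    "status",
]


@dataclass
class AnalysisConfig:
    """Settings shared by the pipeline entry points."""

    alpha: float = 0.05
    ratios: list[str] | None = None  # None -> full default library
    quantitative_ratio: str = "3:1"
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_restarts: int = 10
    seed: int = 0
    traits: list[str] | None = None  # None -> every numeric trait column
    out_dir: Path | None = None
    # synthetic block (end-to-end runs)
    n_plants: int = 187
    separation_sd: float = 4.5
    shared_variance_fraction: float = 0.0
    render_masks: bool = False
    mask_scale: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def library(self) -> RatioLibrary:
        lib = RatioLibrary()
        return lib.subset(self.ratios) if self.ratios else lib

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_qualitative(
    counts: list[SegregationCounts],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Screen each trait's observed split against the ratio battery.

    Returns the report table (one row per trait x ratio); when
    ``config.out_dir`` is set, writes ``qualitative_report.tsv`` (chi2 and p
    rounded to 3 decimals) and a full-precision JSON sidecar.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    library = config.library()
    rows = []
    for c in counts:
        for res in ratio_battery(c, library, alpha=config.alpha):
            rows.append(
                {
                    "trait": res.trait,
                    "model": res.model_name,
                    "observed_dom": res.observed[0],
                    "observed_rec": res.observed[1],
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p_value,
                    "rejected": res.rejected,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["trait", "model", "observed_dom", "observed_rec", "chi2", "df", "p", "rejected"],
    )
    if not counts:
        logger.warning("qualitative: empty counts input, writing empty report")
    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        display = report.copy()
        if len(display):
            display["chi2"] = display["chi2"].round(3)
            display["p"] = display["p"].round(3)
        _write_tsv(display, config.out_dir / "qualitative_report.tsv")
        _write_json(rows, config.out_dir / "qualitative_report.json")
    logger.info(
        "qualitative: %d traits x %d ratios, alpha=%g (%.2fs)",
        len(counts),
        len(library),
        config.alpha,
        time.perf_counter() - t0,
    )
    return report


def _em_seed(base_seed: int, trait: str, projection: int) -> int:
    # stable per-(trait, projection) child seed, independent of processing order
    return int(
        np.random.SeedSequence(
            entropy=base_seed, spawn_key=(zlib.crc32(trait.encode()) & 0xFFFF, projection)
        ).generate_state(1)[0]
        % (2**31)
    )


def run_quantitative(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixture-split every trait per projection and test the split ratio.

    Parameters
    ----------
    table:
        Trait table indexed by (plant_id, projection); every selected column
        is analysed independently per projection.
    config:
        EM settings, alpha, the tested ratio and the output directory.

    Returns
    -------
    (report, verdicts):
        ``report`` has one row per trait x projection with the mixture and
        chi-square summary; a projection with too few observations is kept as
        a row with ``status='failed'``.  ``verdicts`` has one row per trait
        with ``consistent`` True/False, or ``not_evaluable`` status when any
        of the four projections is missing or failed.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    model = RatioLibrary().get(config.quantitative_ratio)
    traits = config.traits or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    projections = (1, 2, 3, 4)
    rows: list[dict] = []
    verdict_rows: list[dict] = []
    for trait in traits:
        per_proj_results: dict[int, ChiSquareResult] = {}
        for proj in projections:
            try:
                values = table.xs(proj, level="projection")[trait].dropna().to_numpy()
            except KeyError:
                values = np.array([])
            row: dict = {"trait": trait, "projection": proj}
            if len(values) < 8:
                row.update({c: np.nan for c in S3_COLUMNS[2:-1]})
                row["status"] = "failed: fewer than 8 observations"
                rows.append(row)
                continue
            try:
                fit = em_fit(
                    values,
                    tol=config.em_tol,
                    max_iter=config.em_max_iter,
                    restarts=config.em_restarts,
                    seed=_em_seed(config.seed, trait, proj),
                )
            except ValueError as exc:
                row.update({c: np.nan for c in S3_COLUMNS[2:-1]})
                row["status"] = f"failed: {exc}"
                logger.warning("quantitative: %s p%d failed: %s", trait, proj, exc)
                rows.append(row)
                continue
            counts = mixture_to_segregation(fit, trait=trait)
            res = pearson_chi2(counts, model, alpha=config.alpha)
            per_proj_results[proj] = res
            c1, c2 = fit.components
            num1 = int(np.sum(fit.assignments == 0))
            num2 = len(fit.assignments) - num1
            if not fit.converged:
                logger.warning("quantitative: %s p%d EM did not converge", trait, proj)
            row.update(
                {
                    "mean1": c1.mean,
                    "var1": c1.variance,
                    "mean2": c2.mean,
                    "var2": c2.variance,
                    "num1": num1,
                    "num2": num2,
                    "numratio_1vs2": num1 / num2 if num2 else np.inf,
                    "chisq": res.chi2,
                    "chisq_p": res.p_value,
                    "status": "ok",
                }
            )
            rows.append(row)
        if len(per_proj_results) == 4:
            verdict = projection_consistency([per_proj_results[p] for p in projections])
            verdict_rows.append(
                {
                    "trait": trait,
                    "model": model.name,
                    "consistent": verdict.consistent,
                    "status": "evaluated",
                }
            )
        else:
            verdict_rows.append(
                {"trait": trait, "model": model.name, "consistent": False, "status": "not_evaluable"}
            )
    report = pd.DataFrame(rows, columns=S3_COLUMNS)
    verdicts = pd.DataFrame(verdict_rows, columns=["trait", "model", "consistent", "status"])
    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        display = report.copy()
        for col in ("mean1", "var1", "mean2", "var2", "numratio_1vs2", "chisq", "chisq_p"):
            display[col] = display[col].round(3)
        _write_tsv(display, config.out_dir / "quantitative_report.tsv")
        _write_json(rows, config.out_dir / "quantitative_report.json")
        _write_tsv(verdicts, config.out_dir / "consistency_verdicts.tsv")
    logger.info(
        "quantitative: %d traits x 4 projections vs %s, seed=%d (%.2fs)",
        len(traits),
        model.name,
        config.seed,
        time.perf_counter() - t0,
    )
    return report, verdicts


def run_end_to_end(config: AnalysisConfig) -> dict:
    """Simulate a population, run both tracks, and write a run manifest.

    Generates the F2 population and its quantitative trait (optionally by
    rendering spike masks and measuring them), derives the qualitative split
    from the simulated phenotype classes, runs both analysis tracks into
    ``config.out_dir``, and writes ``manifest.json`` recording seeds, sizes
    and output files.  Returns the manifest dict.
    """
    if config.out_dir is None:
        raise ValueError("end-to-end run requires out_dir")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    spec = default_population_spec(
        seed=config.seed,
        n_plants=config.n_plants,
        separation_sd=config.separation_sd,
        shared_variance_fraction=config.shared_variance_fraction,
    )
    stage = "simulate"
    outputs: list[str] = []
    try:
        plants = simulate_f2(spec)
        plants.to_csv(out / "plants.csv", index=False)
        outputs.append("plants.csv")
        if config.render_masks:
            stage = "render+morphometry"
            table = _traits_from_masks(plants, spec, config)
        else:
            table = simulate_traits(plants["phenotype"], spec)
        write_trait_table(table, out / "traits.csv")
        outputs.append("traits.csv")

        stage = "qualitative"
        class_counts = plants["phenotype"].value_counts()
        counts = [
            SegregationCounts.from_unordered(
                spec.trait + "_class",
                [
                    int(class_counts.get(spec.model.dominant_class, 0)),
                    int(class_counts.get(spec.model.recessive_class, 0)),
                ],
            )
        ]
        write_counts_csv(counts, out / "counts.csv")
        outputs.append("counts.csv")
        run_qualitative(counts, config)
        outputs += ["qualitative_report.tsv", "qualitative_report.json"]

        stage = "quantitative"
        run_quantitative(table, config)
        outputs += ["quantitative_report.tsv", "quantitative_report.json", "consistency_verdicts.tsv"]
    except Exception as exc:
        raise RuntimeError(f"end-to-end run failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_plants": config.n_plants,
        "model": spec.model.name,
        "trait": spec.trait,
        "alpha": config.alpha,
        "render_masks": config.render_masks,
        "outputs": outputs,
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def _traits_from_masks(plants: pd.DataFrame, spec: PopulationSpec, config: AnalysisConfig) -> pd.DataFrame:
    """Render per-plant spike masks and measure them into a trait table.

    The recessive (tetraaristatum-like) class receives proportionally more
    awns, so the measured awn area SAA segregates with the genotype split.
    """
    mask_dir = config.out_dir / "masks"
    pairs = []
    for i, row in plants.iterrows():
        recessive = row["phenotype"] == spec.model.recessive_class
        awn_count = 24 if recessive else 8
        for proj in (1, 2, 3, 4):
            spike_spec = SyntheticSpikeSpec(
                awn_count=awn_count,
                scale=config.mask_scale,
                seed=int((config.seed + 1) * 100_000 + i * 10 + proj) % (2**31),
            )
            pair, truth = render_spike(spike_spec, spike_id=row["plant_id"], projection=proj)
            write_mask_pair(pair, mask_dir)
            pairs.append(pair)
    table = build_trait_table(pairs)
    return table.rename_axis(index=["plant_id", "projection"])
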