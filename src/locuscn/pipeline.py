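"""End-to-end orchestration: counts -> ratios -> segmentation -> scores ->
population adjustment -> mixture clustering -> integer CN calls.

Single-population segmentation scores (SSP) are computed within each major
population, pooled scores (SSP_P) from the all-sample run; a per-population
regression of SSP_P on SSP gives comparable final scores.  A user-named (or
auto-selected) reference population with clear clusters provides EM-derived
priors for the Bayesian mixture applied to the full cohort.  All randomness
(segmentation permutations, EM restarts, Gibbs) flows from one root seed via
named substreams, and rerunning with the same seed reproduces every output
byte for byte.
"""
from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import (PopulationFit, ZeroVarianceError, adjust_scores,
                     fit_population_regression, fits_to_frame)
from .diagnostics import heidelberger_welch
from .discovery import (PolymorphicRegions, SubRegionProfile, derive_subregions,
                        identify_polymorphic_region, regions_to_bed,
                        subregion_stats)
from .gibbs import GibbsResult, MCMCSettings, PriorSpec, gibbs_fit
from .intervals import GenomicInterval
from .mixture import (CNCalls, assign_cn, bic_select, choose_K, detect_outliers,
                      em_fit, estimate_grid_spacing)
from .normalize import compute_ratios, standardize
from .scoring import Rule, ScoreParams, gene_score, pooled_gene_score
from .segment import SegmentList, segment_sample, segments_to_frame
from .windows import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Window-size guidance for gene-scale loci: 500 bp for a ~2 kb gene,
    1000 bp for larger targets; windows larger than the gene are refused
    because breakpoints near or inside the gene could no longer be detected.
    """

    gene: str                               # 1-based inclusive region string
    merge_threshold: float = 0.35
    boundary_len_bp: int | None = None      # default: half the window size
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    sd_threshold: float = 0.5
    max_bridge_bp: int | None = None        # default: 5 window widths
    reference_population: str | None = None  # population name, or "auto"
    reference_K: int | None = None          # reference group count (else BIC)
    k_mode: str = "distance"                # "distance" | "bic"
    K: int | None = None                    # explicit override
    prior_distance: float | None = None
    cn_of_first_group: int = 0
    outlier_bound: float | None = None
    use_discovered_region: bool = False
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0


@dataclass
class PipelineResult:
    score_table: pd.DataFrame
    fits: pd.DataFrame
    calls: CNCalls
    calls_table: pd.DataFrame
    profile: SubRegionProfile
    regions: PolymorphicRegions
    gibbs: GibbsResult
    seglists_pooled: list[SegmentList]
    manifest: dict


def _run_segmentation(
    counts: CountMatrix, cfg: RunConfig, seeds: np.ndarray
) -> tuple[list[SegmentList], "np.ndarray", object]:
    ratios = compute_ratios(counts)
    std = standardize(ratios)
    seglists = [
        segment_sample(
            std.x[i],
            std.mask,
            alpha=cfg.alpha,
            n_perm=cfg.n_perm,
            min_width=cfg.min_width,
            seed=int(seeds[i]),
            sample_id=sid,
        )
        for i, sid in enumerate(counts.sample_ids)
    ]
    return seglists, std.x, std


def select_group_count(
    scores: np.ndarray,
    k_mode: str = "distance",
    ref_distances: np.ndarray | None = None,
    prior_distance: float | None = None,
    k_max: int = 12,
    seed: int = 0,
) -> int:
    """Number of CN groups for the cohort's (outlier-free) final scores.

    ``distance`` mode divides the score range by the (reference-derived)
    inter-group distance; ``bic`` mode minimizes BIC over mixture sizes.
    """
    x = np.asarray(scores, dtype=float)
    if k_mode == "bic":
        k_hi = max(1, min(k_max, x.size // 5))
        return bic_select(x, range(1, k_hi + 1), seed=seed)
    if k_mode == "distance":
        if prior_distance is not None:
            distances = np.array([prior_distance])
        elif ref_distances is not None and len(ref_distances):
            distances = np.asarray(ref_distances, dtype=float)
        else:
            raise ValueError("distance mode needs ref_distances or prior_distance")
        return choose_K(float(x.min()), float(x.max()), distances)
    raise ValueError(f"unknown k_mode {k_mode!r}")


def _pick_reference_population(
    table: pd.DataFrame, cfg: RunConfig, seed: int
) -> str:
    populations = sorted(table["population"].unique())
    ref = cfg.reference_population
    if ref is None:
        raise ValueError(
            "reference_population must be set (a population name, or 'auto') "
            "to derive mixture priors"
        )
    if ref != "auto":
        if ref not in populations:
            raise KeyError(f"reference population {ref!r} not in population map")
        return ref
    # auto: best silhouette of the per-population EM clustering
    from sklearn.metrics import silhouette_score

    best, best_score = populations[0], -np.inf
    for pop in populations:
        x = table.loc[table["population"] == pop, "final"].to_numpy()
        if x.size < 10:
            continue
        try:
            k = bic_select(x, range(1, max(2, min(8, x.size // 5)) + 1), seed=seed)
            if k < 2:
                continue
            _, resp = em_fit(x, k, seed=seed)
            labels = resp.argmax(axis=1)
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(x.reshape(-1, 1), labels)
        except (RuntimeError, ValueError):
            continue
        if s > best_score:
            best, best_score = pop, s
    logger.info("auto-selected reference population %s", best)
    return best


def run_full_pipeline(
    counts: CountMatrix,
    popmap: Mapping[str, str] | pd.Series,
    config: RunConfig,
    outdir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Execute the whole method on a count matrix; optionally write artifacts."""
    cfg = config
    grid = counts.grid
    gene = GenomicInterval.from_region(cfg.gene)
    if grid.window_size > gene.length:
        raise ValueError(
            f"window size {grid.window_size} bp exceeds the gene length "
            f"{gene.length} bp; breakpoints near or inside the gene would be "
            "undetectable — use a smaller window"
        )
    popmap = pd.Series(popmap)
    missing = [s for s in counts.sample_ids if s not in popmap.index]
    if missing:
        raise KeyError(f"samples missing from population map: {missing[:5]}")
    populations = sorted(popmap.loc[counts.sample_ids].unique())

    ss = np.random.SeedSequence(cfg.seed)
    seg_child, em_child, gibbs_child = ss.spawn(3)
    seg_rng = np.random.default_rng(seg_child)
    em_seed = int(np.random.default_rng(em_child).integers(2**31))
    gibbs_seed = int(np.random.default_rng(gibbs_child).integers(2**31))
    notices: list[str] = []

    params = ScoreParams(
        window_size=grid.window_size,
        merge_threshold=cfg.merge_threshold,
        boundary_len_bp=cfg.boundary_len_bp,
    )

    # --- pooled run: segmentation, region discovery, pooled scores ---------
    pooled_seeds = seg_rng.integers(0, 2**31, size=len(counts.sample_ids))
    seglists_pooled, _, _ = _run_segmentation(counts, cfg, pooled_seeds)
    subregions = derive_subregions(seglists_pooled)
    profile = subregion_stats(seglists_pooled, subregions, grid)
    regions = identify_polymorphic_region(
        profile, gene, sd_threshold=cfg.sd_threshold,
        max_bridge_bp=cfg.max_bridge_bp,
    )
    if not regions.found:
        notices.append("no CNV region found above the SD threshold at the gene")

    target = gene
    if cfg.use_discovered_region and regions.found:
        target = regions.gene_region
        notices.append(f"scoring discovered region {target.to_region()}")

    pooled_scores = {
        sl.sample_id: pooled_gene_score(sl, target, grid)
        for sl in seglists_pooled
    }

    # --- per-population runs: SSP ------------------------------------------
    rows = []
    for pop in populations:
        ids = [s for s in counts.sample_ids if popmap[s] == pop]
        sub = counts.subset(ids)
        seeds = seg_rng.integers(0, 2**31, size=len(ids))
        seglists, x, _ = _run_segmentation(sub, cfg, seeds)
        for i, sl in enumerate(seglists):
            gs = gene_score(sl, target, x[i], grid, params)
            ps = pooled_scores[sl.sample_id]
            rows.append(
                {
                    "sample_id": sl.sample_id,
                    "population": pop,
                    "ssp": gs.score,
                    "ssp_rule": gs.rule.value,
                    "ssp_p": ps.score,
                    "ssp_p_rule": ps.rule.value,
                }
            )
    table = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(counts.sample_ids)}
    table = table.sort_values("sample_id", key=lambda c: c.map(order))
    table = table.reset_index(drop=True)

    # --- cross-population adjustment ---------------------------------------
    fits: dict[str, PopulationFit] = {}
    if len(populations) < 2:
        notices.append("single population: adjustment skipped, final = SSP")
        table["final"] = table["ssp"]
    else:
        fallback_pops = []
        for pop in populations:
            sub = table[table["population"] == pop]
            try:
                fits[pop] = fit_population_regression(
                    sub["ssp"].to_numpy(), sub["ssp_p"].to_numpy(), pop
                )
            except ZeroVarianceError:
                fallback_pops.append(pop)
                notices.append(
                    f"population {pop}: SSP variance zero, final = SSP_P"
                )
        table = adjust_scores(table, fits) if fits else table.assign(final=np.nan)
        for pop in fallback_pops:
            sel = table["population"] == pop
            table.loc[sel, "final"] = table.loc[sel, "ssp_p"]

    # --- outliers ----------------------------------------------------------
    final = table["final"].to_numpy()
    if cfg.outlier_bound is not None:
        kept_scores, outlier_idx = detect_outliers(final, cfg.outlier_bound)
    else:
        kept_scores, outlier_idx = final.copy(), np.array([], dtype=int)
    outlier_mask = np.zeros(final.size, dtype=bool)
    outlier_mask[outlier_idx] = True

    # --- reference-population EM priors ------------------------------------
    ref_pop = _pick_reference_population(table, cfg, em_seed)
    ref_scores = table.loc[
        (table["population"] == ref_pop) & ~outlier_mask, "final"
    ].to_numpy()
    k_hi = max(1, min(10, ref_scores.size // 5))
    if cfg.reference_K is not None:
        k_ref = min(int(cfg.reference_K), k_hi)
    else:
        k_ref = bic_select(ref_scores, range(1, k_hi + 1), seed=em_seed)
        if k_ref == 1 and cfg.K is not None and cfg.K > 1:
            # BIC under-resolves small references; the user's group count
            # bounds how many groups the reference can be expected to show
            k_ref = min(int(cfg.K), k_hi)
            notices.append(
                f"reference BIC chose 1 group; refitting with {k_ref}"
            )
    while k_ref > 1:
        try:
            ref_model, _ = em_fit(ref_scores, k_ref, seed=em_seed)
            break
        except RuntimeError:
            k_ref -= 1
            notices.append(f"reference EM collapsed; retrying with {k_ref}")
    else:
        ref_model, _ = em_fit(ref_scores, 1, seed=em_seed)

    # --- group count and Bayesian clustering -------------------------------
    if cfg.K is not None:
        K = int(cfg.K)
    else:
        ref_d = (
            [estimate_grid_spacing(ref_model)] if ref_model.K >= 2 else None
        )
        K = select_group_count(
            kept_scores,
            k_mode=cfg.k_mode,
            ref_distances=ref_d,
            prior_distance=cfg.prior_distance,
            seed=em_seed,
        )
    prior = PriorSpec.from_reference(
        ref_model, distance=cfg.prior_distance, data=kept_scores
    )
    mcmc = dataclasses.replace(cfg.mcmc, seed=gibbs_seed)
    kept_ids = [s for s, o in zip(table["sample_id"], outlier_mask) if not o]
    gibbs = gibbs_fit(kept_scores, K, prior, mcmc, sample_ids=kept_ids)
    notices.extend(gibbs.warnings)

    # --- merge outliers back, assign integer CN ----------------------------
    n = final.size
    probs = np.zeros((n, K))
    group = np.zeros(n, dtype=int)
    probs[~outlier_mask] = gibbs.calls.probs
    group[~outlier_mask] = gibbs.calls.group
    probs[outlier_mask, K - 1] = 1.0   # outliers: largest group, probability 1
    group[outlier_mask] = K - 1
    calls = CNCalls(list(table["sample_id"]), group, probs, outlier_mask)
    calls = assign_cn(calls, cfg.cn_of_first_group)
    calls_table = calls.to_frame(table["population"].to_numpy(), final)

    # --- convergence diagnostics on the mean chains ------------------------
    hw = [
        heidelberger_welch(gibbs.chains["mu"][:, k]).passed for k in range(K)
    ]

    manifest = {
        "package": {"name": "locuscn", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(cfg).items()
                if k != "mcmc"
            },
            "mcmc": dataclasses.asdict(cfg.mcmc),
        },
        "grid": {
            "contig": grid.contig,
            "region": grid.region.to_region(),
            "window_size": grid.window_size,
            "n_windows": grid.n_windows,
        },
        "populations": populations,
        "reference_population": ref_pop,
        "reference_K": int(k_ref),
        "K": int(K),
        "n_outliers": int(outlier_mask.sum()),
        "mu_chain_hw_passed": [bool(v) for v in hw],
        "notices": notices,
    }
    for note in notices:
        logger.info("%s", note)

    result = PipelineResult(
        table, fits_to_frame(fits), calls, calls_table, profile, regions,
        gibbs, seglists_pooled, manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir, grid)
    return result


def write_outputs(result: PipelineResult, outdir, grid) -> None:
    os.makedirs(outdir, exist_ok=True)

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    fmt = "%.8g"
    result.score_table.to_csv(path("scores.tsv"), sep="\t", index=False,
                              float_format=fmt)
    result.fits.to_csv(path("fits.tsv"), sep="\t", index=False, float_format=fmt)
    result.calls_table.to_csv(path("calls.tsv"), sep="\t", index=False,
                              float_format=fmt)
    result.profile.to_frame().to_csv(path("profile.tsv"), sep="\t", index=False,
                                     float_format=fmt)
    with open(path("regions.bed"), "w") as fh:
        fh.write(regions_to_bed(result.regions.runs))
    segments_to_frame(result.seglists_pooled, grid).to_csv(
        path("segments_pooled.tsv"), sep="\t", index=False, float_format=fmt
    )
    with open(path("manifest.yaml"), "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)
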