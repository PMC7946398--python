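"""Orchestration of the in-silico calcium-scoring study.

A study run sweeps dose levels (detector frame averages) x reconstruction
methods (FBP, TV- and gamma-regularized IR) x regularization policies,
scores every reconstruction (Agatston score, calcium volume, CAD grade per
insert), measures image quality, and applies the statistical comparison
layer: Wilcoxon signed-rank tests against the low-noise FBP reference,
Friedman tests with Bonferroni-corrected post-hoc Wilcoxon across the three
fixed regularization strengths, Pearson correlation, Bland-Altman limits of
agreement, and CAD-grade reclassification rates.

The nine inserts are the paired observations throughout.  Everything is
reproducible from the study configuration and a single integer seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from cacstudy import cac_score, fanbeam_sim, iq_metrics, recon_fbp, recon_ir, reg_select
from cacstudy.cac_score import ScoringConfig
from cacstudy.fanbeam_sim import FanBeamGeometry
from cacstudy.phantom_forge import (
    GridSpec,
    MaterialModel,
    PhantomVolume,
    build_cardiac_rod,
    build_epoxy_rod,
    study_inserts,
)
from cacstudy.recon_fbp import FbpKernel

#: protocol labels -> frame averages (low-/clinical-/high-noise protocols)
PROTOCOL_FRAMES = {"LNP": 15, "CNP": 2, "HNP": 1}


# ---------------------------------------------------------------------------
# statistics layer


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p, zero differences discarded.

    Uses the exact null distribution when the informative sample is small
    and tie-free.  All-zero differences return p = 1 by convention.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    mode = "exact" if d.size <= 25 and np.unique(np.abs(d)).size == d.size else "auto"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", mode=mode)
    return float(res.pvalue)


def friedman_with_posthoc(blocks: np.ndarray, alpha: float = 0.05):
    """Friedman test over blocks x treatments plus pairwise Bonferroni post hoc.

    Returns (friedman_p, {pair: corrected_p}, bonferroni_threshold).
    The corrected threshold for 3 treatments is alpha/3 ~= 0.017.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2 or blocks.shape[0] < 3 or blocks.shape[1] < 3:
        raise ValueError("need >= 3 blocks and >= 3 treatments")
    k = blocks.shape[1]
    if np.all(blocks == blocks[:, :1]):
        friedman_p = 1.0
    else:
        _, friedman_p = sps.friedmanchisquare(*[blocks[:, j] for j in range(k)])
    n_pairs = k * (k - 1) // 2
    posthoc = {}
    for i, j in itertools.combinations(range(k), 2):
        p = wilcoxon_signed_rank(blocks[:, i], blocks[:, j])
        posthoc[(i, j)] = min(1.0, p * n_pairs)
    return float(friedman_p), posthoc, alpha / n_pairs


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement: bias +/- 1.96 SD of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def pearson_r(a, b) -> tuple[float, float]:
    """Product-moment correlation with its t-distribution p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# study configuration


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run.

    The defaults are the desk-scale study conditions: a 128x128 grid
    (0.75 mm in-plane), 180 views, a 256-channel detector covering the rod,
    dose levels of 1/2/15 frame averages (the HNP/CNP/LNP protocols) with
    three noise realizations each, and 100 Barzilai-Borwein iterations.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    geometry: FanBeamGeometry = field(default_factory=lambda: fanbeam_sim.desk_geometry())
    materials: MaterialModel = field(default_factory=MaterialModel)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    frames_levels: tuple = (1, 2, 15)
    seeds: tuple = (1, 2, 3)
    methods: tuple = ("FBP", "TV", "GAMMA")
    target_lnp_noise: float = 7.4  # HU, FBP noise at 15 frame averages
    ir_iterations: int = 100
    n_lambda_candidates: int = 12
    kernel: FbpKernel = field(default_factory=FbpKernel)
    reference_frames: int = 15  # LNP/FBP is the scoring reference
    include_adaptive: bool = False  # adaptive-lambda tables for every dose level
    i0_per_frame: float | None = None  # calibrated when None
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.reference_frames not in self.frames_levels:
            raise ValueError("reference protocol must be among the dose levels")
        for frames in PROTOCOL_FRAMES.values():
            if not 1 <= frames <= fanbeam_sim.FRAMES_FULL:
                raise ValueError("protocol labels must map to valid frame counts")


def desk_study_config(**overrides) -> StudyConfig:
    """The desk-scale study configuration (see StudyConfig defaults)."""
    return StudyConfig(**overrides)


# ---------------------------------------------------------------------------
# study execution


@dataclass
class StudyResult:
    config: StudyConfig
    seed: int
    i0_per_frame: float
    lambda_tables: pd.DataFrame  # per method: weak/medium/strong (+ adaptive)
    scores: pd.DataFrame  # per (method, strength, frames, seed, insert)
    iq: pd.DataFrame  # per (method, strength, frames, seed): noise, cnr, f50
    noise_benchmarks: pd.DataFrame  # epoxy-rod noise per (method, strength, frames, seed)
    reclassification: pd.DataFrame  # per (method, frames): rate vs LNP/FBP
    comparisons: dict  # statistics vs the reference protocol

    def save(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out_dir / "score_tables.csv", index=False)
        self.iq.to_csv(out_dir / "iq_metrics.csv", index=False)
        self.noise_benchmarks.to_csv(out_dir / "noise_benchmarks.csv", index=False)
        self.lambda_tables.to_csv(out_dir / "lambda_tables.csv", index=False)
        self.reclassification.to_csv(out_dir / "reclassification.csv", index=False)
        report = {
            "seed": self.seed,
            "i0_per_frame": self.i0_per_frame,
            "comparisons": self.comparisons,
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))


def _child_seed(base_seed: int, *ids: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in ids]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _scoring_roi(phantom: PhantomVolume) -> np.ndarray:
    """Rod interior, excluding the air-gap neighborhood, on voxel slices."""
    from scipy import ndimage

    from cacstudy.phantom_forge import LABEL_AIR_GAP

    roi = phantom.rod_mask()
    if phantom.gap is not None:
        gap = phantom.labels == LABEL_AIR_GAP
        for k in range(roi.shape[0]):
            roi[k] &= ~ndimage.binary_dilation(gap[k], iterations=3)
    return roi


class _StudyEngine:
    """Holds the shared state of one study run (phantoms, operator, i0)."""

    def __init__(self, config: StudyConfig, seed: int, verbose: bool = False):
        self.config = config
        self.seed = seed
        self.verbose = verbose
        self.grid = config.grid
        self.geom = config.geometry
        self.materials = config.materials
        self.cardiac = build_cardiac_rod(study_inserts(), self.grid, self.materials)
        self.epoxy = build_epoxy_rod(self.grid, self.materials)
        self.bench_k = self.grid.nz // 2
        self.noise_roi = self.cardiac.background_mask()[self.bench_k]
        self.epoxy_roi = self.epoxy.interior_mask()[self.bench_k]
        self.scoring_roi = _scoring_roi(self.cardiac)
        self.heart_roi, self.bg_roi = self._cnr_rois()
        self._ideal_cardiac = {}  # slice index -> ideal sinogram
        self._ideal_epoxy = None

        self.i0 = config.i0_per_frame
        if self.i0 is None:
            self.log("calibrating i0 for the LNP noise target")
            self.i0 = fanbeam_sim.calibrate_i0(
                config.target_lnp_noise, self.cardiac, self.geom, config.kernel,
                seed=_child_seed(seed, 999),
            )
        self.log(f"i0_per_frame = {self.i0:.0f}")

    def log(self, msg: str) -> None:
        if self.verbose:
            print(f"[study] {msg}", flush=True)

    def _cnr_rois(self):
        """Ground-truth heart/background masks, eroded, on the bench slice."""
        from scipy import ndimage

        from cacstudy.phantom_forge import LABEL_HEART

        heart = self.cardiac.labels[self.bench_k] == LABEL_HEART
        heart = ndimage.binary_erosion(heart, iterations=2)
        return heart, self.noise_roi

    def ideal_cardiac(self, k: int) -> np.ndarray:
        if k not in self._ideal_cardiac:
            self._ideal_cardiac[k] = fanbeam_sim.project(
                self.cardiac.mu[k], self.geom, (self.grid.dy, self.grid.dx)
            )
        return self._ideal_cardiac[k]

    def ideal_epoxy(self) -> np.ndarray:
        if self._ideal_epoxy is None:
            self._ideal_epoxy = fanbeam_sim.project(
                self.epoxy.mu[self.bench_k], self.geom, (self.grid.dy, self.grid.dx)
            )
        return self._ideal_epoxy

    def cardiac_sinos(self, frames: int, seed: int) -> list:
        out = []
        for k in range(self.grid.nz):
            stack = fanbeam_sim.simulate_counts(
                self.ideal_cardiac(k), self.i0, frames, _child_seed(seed, 1, frames, k)
            )
            out.append(fanbeam_sim.average_and_log(stack, self.geom))
        return out

    def epoxy_sino(self, frames: int, seed: int, slice_tag: int = 0):
        stack = fanbeam_sim.simulate_counts(
            self.ideal_epoxy(), self.i0, frames, _child_seed(seed, 2, frames, slice_tag)
        )
        return fanbeam_sim.average_and_log(stack, self.geom)

    def score_volume(self, volume_hu: np.ndarray) -> pd.DataFrame:
        return cac_score.score_table(
            volume_hu, self.grid.dz, (self.grid.dy, self.grid.dx),
            self.cardiac.inserts, self.config.scoring, roi_mask=self.scoring_roi,
        )

    def iq_row(self, bench_image: np.ndarray) -> dict:
        return {
            "noise_hu": iq_metrics.noise_sd(bench_image, self.noise_roi),
            "cnr": iq_metrics.cnr(bench_image, self.heart_roi, self.bg_roi),
            "f50_cyc_mm": iq_metrics.mtf_from_gap(
                bench_image, self.cardiac.gap, (self.grid.dy, self.grid.dx)
            ).f50,
        }


def select_lambdas(engine: _StudyEngine, regularizer: str):
    """Candidate grid, adaptive pick and MTF-matched fixed levels at LNP."""
    cfg = engine.config
    sino = fanbeam_sim.average_and_log(
        fanbeam_sim.simulate_counts(
            engine.ideal_cardiac(engine.bench_k), engine.i0, cfg.reference_frames,
            _child_seed(engine.seed, 777),
        ),
        engine.geom,
    )
    fbp_bench = recon_fbp.fbp(sino, cfg.kernel, engine.grid, engine.materials).image
    lam_grid = reg_select.lambda_grid_for(
        sino, engine.geom, engine.grid, engine.materials, regularizer,
        n_candidates=cfg.n_lambda_candidates,
    )
    images = reg_select.batch_reconstruct(
        sino, engine.geom, engine.grid, engine.materials, regularizer, lam_grid,
        cfg.ir_iterations,
    )
    adaptive = reg_select.adaptive_lambda(
        sino, engine.geom, engine.grid, engine.materials, regularizer, lam_grid,
        cfg.target_lnp_noise, engine.noise_roi, images=images,
    )
    medium = reg_select.mtf_match_lambda(
        fbp_bench, dict(zip(map(float, lam_grid), images)), engine.cardiac.gap,
        (engine.grid.dy, engine.grid.dx),
    )
    levels = reg_select.fixed_levels_from_grid(lam_grid, medium)
    engine.log(
        f"{regularizer}: weak/medium/strong = "
        f"{levels['weak']:.3g}/{levels['medium']:.3g}/{levels['strong']:.3g}, "
        f"adaptive(LNP) = {adaptive.lam:.3g}"
    )
    return lam_grid, levels, adaptive


def run_study(config: StudyConfig, seed: int = 1, verbose: bool = False) -> StudyResult:
    """Execute the full study for one base seed; see the module docstring."""
    engine = _StudyEngine(config, seed, verbose)
    grid, geom, materials = config.grid, config.geometry, config.materials
    ir_regs = [m for m in config.methods if m != "FBP"]
    strengths = ("weak", "medium", "strong")

    # --- regularization selection at the reference dose
    lam_rows, levels_by_reg = [], {}
    for reg in ir_regs:
        lam_grid, levels, adaptive = select_lambdas(engine, reg)
        levels_by_reg[reg] = levels
        for name in strengths:
            lam_rows.append({"method": reg, "level": name, "lambda": levels[name]})
        lam_rows.append({"method": reg, "level": "adaptive_lnp", "lambda": adaptive.lam})
        if config.include_adaptive:
            for frames in config.frames_levels:
                if frames == config.reference_frames:
                    continue
                sino = engine.cardiac_sinos(frames, _child_seed(engine.seed, 778, frames))[engine.bench_k]
                res = reg_select.adaptive_lambda(
                    sino, geom, grid, materials, reg, lam_grid,
                    config.target_lnp_noise, engine.noise_roi,
                    n_iterations=config.ir_iterations,
                )
                lam_rows.append(
                    {"method": reg, "level": f"adaptive_frames{frames}", "lambda": res.lam}
                )

    score_rows, iq_rows, noise_rows = [], [], []

    def record(method, strength, frames, s, volume_hu):
        table = engine.score_volume(volume_hu)
        table.insert(0, "method", method)
        table.insert(1, "strength", strength)
        table.insert(2, "frames", frames)
        table.insert(3, "seed", s)
        score_rows.append(table)
        row = {"method": method, "strength": strength, "frames": frames, "seed": s}
        row.update(engine.iq_row(volume_hu[engine.bench_k]))
        iq_rows.append(row)

    # --- FBP at every dose level (includes the LNP reference)
    for frames in config.frames_levels:
        for s in config.seeds:
            sinos = engine.cardiac_sinos(frames, _child_seed(seed, 3, frames, s))
            vol = recon_fbp.fbp_volume(sinos, config.kernel, grid, materials)
            record("FBP", "-", frames, s, vol)
            ep = recon_fbp.fbp(engine.epoxy_sino(frames, s), config.kernel, grid, materials)
            noise_rows.append(
                {"method": "FBP", "strength": "-", "frames": frames, "seed": s,
                 "noise_hu": iq_metrics.noise_sd(ep.image, engine.epoxy_roi)}
            )

    # --- IR: full weak/medium/strong volumes at the reference dose,
    #     medium-only volumes off-reference, epoxy noise benchmarks everywhere
    for reg in ir_regs:
        levels = levels_by_reg[reg]
        for s in config.seeds:
            # reference dose: one 18-column batch (3 strengths x 6 slices)
            sinos = engine.cardiac_sinos(config.reference_frames, _child_seed(seed, 3, config.reference_frames, s))
            batch_sinos, batch_lams, keys = [], [], []
            for name in strengths:
                batch_sinos += sinos
                batch_lams += [levels[name]] * len(sinos)
                keys.append(name)
            cfg_ir = recon_ir.IrConfig(regularizer=reg, n_iterations=config.ir_iterations)
            recs, _ = recon_ir.solve_batch(batch_sinos, geom, grid, materials, batch_lams, cfg_ir)
            for i, name in enumerate(keys):
                vol = np.stack([r.image for r in recs[i * len(sinos) : (i + 1) * len(sinos)]])
                record(reg, name, config.reference_frames, s, vol)
            # off-reference doses: medium strength only
            off = [f for f in config.frames_levels if f != config.reference_frames]
            batch_sinos, batch_lams, spans = [], [], []
            for frames in off:
                sl = engine.cardiac_sinos(frames, _child_seed(seed, 3, frames, s))
                batch_sinos += sl
                batch_lams += [levels["medium"]] * len(sl)
                spans.append((frames, len(sl)))
            if batch_sinos:
                recs, _ = recon_ir.solve_batch(batch_sinos, geom, grid, materials, batch_lams, cfg_ir)
                pos = 0
                for frames, n in spans:
                    vol = np.stack([r.image for r in recs[pos : pos + n]])
                    record(reg, "medium", frames, s, vol)
                    pos += n
        # epoxy noise benchmarks: all strengths x all dose levels x seeds
        batch_sinos, batch_lams, keys = [], [], []
        for frames in config.frames_levels:
            for s in config.seeds:
                sino = engine.epoxy_sino(frames, s)
                for name in strengths:
                    batch_sinos.append(sino)
                    batch_lams.append(levels[name])
                    keys.append((name, frames, s))
        cfg_ir = recon_ir.IrConfig(regularizer=reg, n_iterations=config.ir_iterations)
        recs, _ = recon_ir.solve_batch(batch_sinos, geom, grid, materials, batch_lams, cfg_ir)
        for (name, frames, s), rec in zip(keys, recs):
            noise_rows.append(
                {"method": reg, "strength": name, "frames": frames, "seed": s,
                 "noise_hu": iq_metrics.noise_sd(rec.image, engine.epoxy_roi)}
            )
        engine.log(f"{reg}: reconstruction sweep done")

    scores = pd.concat(score_rows, ignore_index=True)
    iq = pd.DataFrame(iq_rows)
    noise_benchmarks = pd.DataFrame(noise_rows)
    lambda_tables = pd.DataFrame(lam_rows)

    # --- reclassification vs the seed-matched LNP/FBP reference
    recl_rows = []
    ref = scores[
        (scores.method == "FBP") & (scores.frames == config.reference_frames)
    ].set_index(["seed", "insert_id"])
    for method in config.methods:
        strength = "-" if method == "FBP" else "medium"
        for frames in config.frames_levels:
            sel = scores[
                (scores.method == method) & (scores.frames == frames) & (scores.strength == strength)
            ]
            if sel.empty:
                continue
            grades = list(sel.grade)
            ref_grades = [ref.loc[(row.seed, row.insert_id)].grade for row in sel.itertuples()]
            recl_rows.append(
                {"method": method, "frames": frames,
                 "rate_percent": cac_score.reclassification_rate(grades, ref_grades)}
            )
    reclassification = pd.DataFrame(recl_rows)

    comparisons = _comparison_report(config, scores)

    result = StudyResult(
        config=config,
        seed=seed,
        i0_per_frame=float(engine.i0),
        lambda_tables=lambda_tables,
        scores=scores,
        iq=iq,
        noise_benchmarks=noise_benchmarks,
        reclassification=reclassification,
        comparisons=comparisons,
    )
    if config.output_dir is not None:
        result.save(config.output_dir)
    return result


def _comparison_report(config: StudyConfig, scores: pd.DataFrame) -> dict:
    """Statistics versus the LNP/FBP reference, per seed (9 inserts paired)."""
    report: dict = {}
    for s in config.seeds:
        ref = scores[
            (scores.method == "FBP")
            & (scores.frames == config.reference_frames)
            & (scores.seed == s)
        ].sort_values("insert_id")
        entry: dict = {}
        for method in config.methods:
            strength = "-" if method == "FBP" else "medium"
            for frames in config.frames_levels:
                if frames == config.reference_frames and method == "FBP":
                    continue
                sel = scores[
                    (scores.method == method)
                    & (scores.frames == frames)
                    & (scores.strength == strength)
                    & (scores.seed == s)
                ].sort_values("insert_id")
                if sel.empty:
                    continue
                key = f"{method}_frames{frames}"
                bias, lo, hi = bland_altman(sel.score.values, ref.score.values)
                try:
                    r, rp = pearson_r(sel.score.values, ref.score.values)
                except ValueError:
                    r, rp = float("nan"), float("nan")
                entry[key] = {
                    "wilcoxon_p_score": wilcoxon_signed_rank(sel.score.values, ref.score.values),
                    "wilcoxon_p_volume": wilcoxon_signed_rank(sel.volume_mm3.values, ref.volume_mm3.values),
                    "pearson_r": r,
                    "pearson_p": rp,
                    "ba_bias": bias,
                    "ba_loa": [lo, hi],
                }
        for method in [m for m in config.methods if m != "FBP"]:
            cols = []
            for level in ("weak", "medium", "strong"):
                sel = scores[
                    (scores.method == method)
                    & (scores.frames == config.reference_frames)
                    & (scores.strength == level)
                    & (scores.seed == s)
                ].sort_values("insert_id")
                cols.append(sel.score.values)
            if all(len(c) for c in cols):
                blocks = np.stack(cols, axis=1)
                p, posthoc, thr = friedman_with_posthoc(blocks)
                entry[f"{method}_friedman"] = {
                    "p": p,
                    "posthoc": {f"{i}-{j}": v for (i, j), v in posthoc.items()},
                    "bonferroni_threshold": thr,
                }
        report[f"seed{s}"] = entry
    return report
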