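"""Synthetic cohorts with planted ground truth for every pipeline stage.

Each subject gets (i) DCM parameters drawn around the qualitative
best-model structure — positive fixed connectivity with a mid-apex
efferent/afferent asymmetry, excitatory bottom-up stimulus-domain
modulations, an excitatory Temporal and inhibitory rostral Contextual
top-down set; (ii) condition-wise reaction times reproducing the
Delay-easy / Dual-hard control interaction with no stimulus-domain
effect; (iii) a correlated five-test ability battery; and (iv) optionally
BOLD simulated from the generative model under the blocked design.

Latent subject factors (top-down magnitude, bottom-up magnitude,
hierarchical asymmetry, trait ability) are drawn from a planted
correlation matrix so that pipeline-recovered brain-behavior
relationships have known targets.  Subjects whose effective connectivity
would be unstable have their deviations shrunk toward the population
mean; every shrink is logged in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CELLS, Design, build_input_timeline, events_frame, generate_design
from .hierarchy import hierarchy_profile
from .modelspace import ModelSpec, default_winning_structure
from .regions import DEFAULT_GEOMETRY, REGIONS
from .simulate import DCMParameters, HemodynamicParams, ROITimeSeries, simulate_dataset

ABILITY_TESTS = ("letter_span", "spatial_span", "operation_span", "symmetry_span", "ravens")

#: condition order used by RT tables (the 8 design cells)
CONDITION_NAMES = tuple(f"{c.stimulus_domain}_{c.subtask_name}" for c in CELLS)

_RT_CURRENT = {"Control": 720.0, "Restart": 820.0, "Delay": 650.0, "Dual": 950.0}
_RT_FUTURE = {"Control": 700.0, "Restart": 830.0, "Delay": 780.0, "Dual": 900.0}


@dataclass
class CohortConfig:
    """Population-level settings of the synthetic cohort.

    Planted correlations relate the latent factors (top-down, bottom-up,
    hierarchical asymmetry, ability); the correlation matrix they imply
    must be positive semidefinite.  Magnitude means/SDs are in Hz.
    """

    n_subjects: int = 24
    # planted latent correlations
    r_topdown_ability: float = 0.5
    r_hier_ability: float = 0.5
    r_topdown_bottomup: float = -0.5
    # modulation magnitudes
    topdown_mean: float = 0.25
    topdown_sd: float = 0.1
    bottomup_mean: float = 0.25
    bottomup_sd: float = 0.1
    min_magnitude: float = 0.02
    b_entry_sd: float = 0.03
    # fixed connectivity
    a_base: float = 0.10
    a_asym: float = 0.06
    a_entry_sd: float = 0.02
    hier_scale_sd: float = 0.3
    a_self: float = -0.5
    c_drive: float = 0.5
    # ability battery
    ability_loadings: tuple[float, ...] = (0.85, 0.8, 0.8, 0.75, 0.75)
    # reaction times (ms)
    rt_subject_sd: float = 50.0
    rt_cell_sd: float = 20.0
    # zone activations for the RT-gradient analysis
    activation_noise_sd: float = 0.4
    # BOLD
    simulate_bold: bool = True
    noise_sd: float = 0.3
    noise_model: str = "white"
    tr: float = 2.0
    dt: float = 0.125
    trial_soa: float = 2.0
    protocol: dict | None = None
    # stability control
    stability_margin: float = 0.02
    max_shrink: int = 40

    def latent_correlation(self) -> np.ndarray:
        r_tg, r_hg, r_tb = self.r_topdown_ability, self.r_hier_ability, self.r_topdown_bottomup
        # order: topdown, bottomup, hier, ability
        return np.array(
            [
                [1.0, r_tb, 0.0, r_tg],
                [r_tb, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, r_hg],
                [r_tg, 0.0, r_hg, 1.0],
            ]
        )


@dataclass
class GroundTruth:
    """Everything needed to recompute any planted quantity."""

    config: CohortConfig
    spec: ModelSpec
    seed: int
    latents: pd.DataFrame  # subject x (topdown, bottomup, hier, ability)
    params: list[DCMParameters]
    vertex_heights: np.ndarray
    strengths: pd.DataFrame
    shrink_log: list[tuple[int, int]] = field(default_factory=list)  # (subject, n_shrinks)


@dataclass
class Cohort:
    truth: GroundTruth
    modulations: pd.DataFrame  # subject x named B entries
    topdown_columns: list[str]
    bottomup_columns: list[str]
    ability: pd.DataFrame  # subject x tests
    rt_current: pd.DataFrame  # subject x condition
    rt_future: pd.DataFrame
    activations: np.ndarray  # (subjects, conditions, 3 zones: caudal, mid, rostral)
    design: Design | None = None
    bold: list[ROITimeSeries] | None = None

    @property
    def n_subjects(self) -> int:
        return self.ability.shape[0]


def _mid_apex_score(y: float) -> float:
    """Rostral/caudal weighting peaking in mid LPFC (y ~ 20 mm)."""
    return 1.0 - ((y - 20.0) / 30.0) ** 2


def _stable(A: np.ndarray, Bstack: np.ndarray, margin: float) -> bool:
    """Stability of every attainable modulated coupling state.

    The modulatory channels attained by the design are one stimulus-domain
    channel at a time, optionally combined with Contextual and/or Temporal.
    """
    combos = []
    for dom in (0, 1):
        for ctx in (0, 1):
            for tmp in (0, 1):
                u = np.zeros(Bstack.shape[0])
                u[dom] = 1.0
                u[2] = ctx
                u[3] = tmp
                combos.append(u)
    combos.append(np.zeros(Bstack.shape[0]))
    for u in combos:
        M = A + np.tensordot(u, Bstack, axes=1)
        if np.max(np.linalg.eigvals(M).real) > -margin:
            return False
    return True


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Draw a full synthetic cohort with planted effect structure."""
    cfg = config or CohortConfig()
    if cfg.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    corr = cfg.latent_correlation()
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("planted correlation matrix is not positive semidefinite")
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects
    spec = default_winning_structure()
    geometry = DEFAULT_GEOMETRY

    # latent subject factors
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    latents = rng.standard_normal((n, 4)) @ L.T
    lat = pd.DataFrame(latents, columns=["topdown", "bottomup", "hier", "ability"])

    td_edges = list(spec.modulation("Temporal")) + list(spec.modulation("Contextual"))
    bu_edges = list(spec.modulation("Spatial")) + list(spec.modulation("Verbal"))
    td_cols = [f"B:Temporal:{d}<-{s}" for s, d in spec.modulation("Temporal")] + [
        f"B:Contextual:{d}<-{s}" for s, d in spec.modulation("Contextual")
    ]
    bu_cols = [f"B:Spatial:{d}<-{s}" for s, d in spec.modulation("Spatial")] + [
        f"B:Verbal:{d}<-{s}" for s, d in spec.modulation("Verbal")
    ]

    scores = {r: _mid_apex_score(geometry.y(r)) for r in REGIONS}
    idx = {r: i for i, r in enumerate(REGIONS)}

    params: list[DCMParameters] = []
    mod_rows = []
    heights = np.empty(n)
    strength_rows = []
    shrink_log: list[tuple[int, int]] = []
    from .design import MOD_CHANNELS

    for s in range(n):
        m_td = max(cfg.min_magnitude, cfg.topdown_mean + cfg.topdown_sd * lat.topdown[s])
        m_bu = max(cfg.min_magnitude, cfg.bottomup_mean + cfg.bottomup_sd * lat.bottomup[s])
        kappa = cfg.a_asym * max(0.0, 1.0 + cfg.hier_scale_sd * lat.hier[s])

        A = np.zeros((6, 6))
        for a, b in spec.edges:
            ia, ib = idx[a], idx[b]
            asym = 0.5 * kappa * (scores[a] - scores[b])
            # clip keeps edge entries positive; non-edges stay exactly zero
            A[ib, ia] = max(0.01, cfg.a_base + asym + cfg.a_entry_sd * rng.standard_normal())
            A[ia, ib] = max(0.01, cfg.a_base - asym + cfg.a_entry_sd * rng.standard_normal())
        np.fill_diagonal(A, cfg.a_self)

        B: dict[str, np.ndarray] = {f: np.zeros((6, 6)) for f in ("Spatial", "Verbal", "Contextual", "Temporal")}
        for src, dst in spec.modulation("Temporal"):
            B["Temporal"][idx[dst], idx[src]] = m_td + cfg.b_entry_sd * rng.standard_normal()
        for src, dst in spec.modulation("Contextual"):
            sign = -1.0 if src == "FPl" else 1.0
            B["Contextual"][idx[dst], idx[src]] = sign * m_td + cfg.b_entry_sd * rng.standard_normal()
        for factor in ("Spatial", "Verbal"):
            for src, dst in spec.modulation(factor):
                B[factor][idx[dst], idx[src]] = m_bu + cfg.b_entry_sd * rng.standard_normal()

        C = np.zeros((6, 3))
        for k, (drive, region) in enumerate(spec.drive_targets):
            C[idx[region], k] = cfg.c_drive

        # shrink deviations toward stability if needed (edge entries only)
        n_shrink = 0
        Bstack = np.stack([B[f] for f in MOD_CHANNELS])
        edge_mask = np.zeros((6, 6), dtype=bool)
        for a, b in spec.edges:
            edge_mask[idx[a], idx[b]] = edge_mask[idx[b], idx[a]] = True
        while not _stable(A, Bstack, cfg.stability_margin):
            n_shrink += 1
            if n_shrink > cfg.max_shrink:
                raise RuntimeError(f"subject {s}: could not stabilize planted parameters")
            Bstack = 0.9 * Bstack
            A[edge_mask] = cfg.a_base + 0.9 * (A[edge_mask] - cfg.a_base)
        if n_shrink:
            shrink_log.append((s, n_shrink))
            B = {f: Bstack[j] for j, f in enumerate(MOD_CHANNELS)}

        p = DCMParameters(regions=REGIONS, A=A, B=B, C=C)
        params.append(p)
        mod_rows.append(
            {col: B[col.split(":")[1]][idx[col.split("<-")[0].split(":")[-1]], idx[col.split("<-")[1]]] for col in td_cols + bu_cols}
        )
        prof = hierarchy_profile(A, geometry, spec.edges)
        heights[s] = prof.vertex.height if not prof.vertex.degenerate else np.nan
        strength_rows.append(prof.strength)

    modulations = pd.DataFrame(mod_rows)
    strengths = pd.DataFrame(strength_rows).reset_index(drop=True)

    # ability battery: five correlated tests loading on the latent
    loadings = np.asarray(cfg.ability_loadings, dtype=float)
    noise = rng.standard_normal((n, loadings.size)) * np.sqrt(np.clip(1.0 - loadings**2, 1e-6, None))
    ability = pd.DataFrame(
        lat.ability.to_numpy()[:, None] * loadings[None, :] + noise, columns=list(ABILITY_TESTS)
    )

    # reaction times: control interaction, no stimulus-domain effect
    subj_off = rng.normal(0.0, cfg.rt_subject_sd, size=n)
    rt_cur = np.empty((n, len(CELLS)))
    rt_fut = np.empty((n, len(CELLS)))
    for j, cond in enumerate(CELLS):
        rt_cur[:, j] = _RT_CURRENT[cond.subtask_name] + subj_off + rng.normal(0.0, cfg.rt_cell_sd, n)
        rt_fut[:, j] = _RT_FUTURE[cond.subtask_name] + subj_off + rng.normal(0.0, cfg.rt_cell_sd, n)
    rt_current = pd.DataFrame(rt_cur, columns=list(CONDITION_NAMES))
    rt_future = pd.DataFrame(rt_fut, columns=list(CONDITION_NAMES))

    # zone activations: caudal tracks current demands, rostral future, mid both
    zc = (rt_cur - rt_cur.mean(axis=1, keepdims=True)) / rt_cur.std(axis=1, ddof=1, keepdims=True)
    zf = (rt_fut - rt_fut.mean(axis=1, keepdims=True)) / rt_fut.std(axis=1, ddof=1, keepdims=True)
    eps = cfg.activation_noise_sd
    activations = np.stack(
        [
            0.8 * zc + eps * rng.standard_normal(zc.shape),
            0.5 * zc + 0.5 * zf + eps * rng.standard_normal(zc.shape),
            0.8 * zf + eps * rng.standard_normal(zc.shape),
        ],
        axis=2,
    )  # zones ordered caudal, mid, rostral

    design = None
    bold = None
    if cfg.simulate_bold:
        design = generate_design(seed=seed, protocol=cfg.protocol)
        timeline = build_input_timeline(design, dt=cfg.dt, trial_soa=cfg.trial_soa)
        bold = []
        child = np.random.SeedSequence(seed).spawn(n)
        for s in range(n):
            bold.append(
                simulate_dataset(
                    params[s],
                    HemodynamicParams(),
                    timeline=timeline,
                    noise_sd=cfg.noise_sd,
                    noise_model=cfg.noise_model,
                    seed=child[s],
                    tr=cfg.tr,
                )
            )

    truth = GroundTruth(
        config=cfg,
        spec=spec,
        seed=seed,
        latents=lat,
        params=params,
        vertex_heights=heights,
        strengths=strengths,
        shrink_log=shrink_log,
    )
    return Cohort(
        truth=truth,
        modulations=modulations,
        topdown_columns=td_cols,
        bottomup_columns=bu_cols,
        ability=ability,
        rt_current=rt_current,
        rt_future=rt_future,
        activations=activations,
        design=design,
        bold=bold,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Serialize a cohort: per-subject time-series CSVs, events TSV,
    cohort-level tables and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.modulations.to_csv(out / "modulations.csv", index=False)
    cohort.ability.to_csv(out / "ability.csv", index=False)
    cohort.rt_current.to_csv(out / "rt_current.csv", index=False)
    cohort.rt_future.to_csv(out / "rt_future.csv", index=False)
    cohort.truth.strengths.to_csv(out / "hierarchical_strengths.csv", index=False)
    if cohort.design is not None:
        events_frame(cohort.design).to_csv(out / "events.tsv", sep="\t", index=False)
    if cohort.bold is not None:
        for s, ts in enumerate(cohort.bold):
            ts.to_csv(out / f"sub-{s:02d}_bold.csv")
    truth = {
        "seed": cohort.truth.seed,
        "spec": json.loads(cohort.truth.spec.to_json()),
        "config": {k: v for k, v in asdict(cohort.truth.config).items()},
        "latents": cohort.truth.latents.to_dict(orient="list"),
        "vertex_heights": cohort.truth.vertex_heights.tolist(),
        "shrink_log": cohort.truth.shrink_log,
        "A": [p.A.tolist() for p in cohort.truth.params],
        "C": [p.C.tolist() for p in cohort.truth.params],
        "B": [{f: m.tolist() for f, m in p.B.items()} for p in cohort.truth.params],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


@dataclass
class RecoveryReport:
    """Recovery of planted quantities by pipeline estimates."""

    parameters: pd.DataFrame  # per-parameter bias, rmse, truth-estimate correlation
    identification_hit_rate: float | None = None
    factor_correlation_error: float | None = None


def recovery_report(
    truth: GroundTruth,
    estimates: pd.DataFrame,
    truth_table: pd.DataFrame | None = None,
    winning_specs: list | None = None,
    recovered_factor_r: float | None = None,
) -> RecoveryReport:
    """Recovery metrics for a cohort analysis.

    ``estimates`` is a subjects x parameters table (columns named like the
    fit labels); ``truth_table`` defaults to the planted values for the
    shared columns.  ``winning_specs`` (one ModelSpec per search run)
    yields the model-identification hit rate against the generating
    structure; ``recovered_factor_r`` yields the error of the recovered
    top-down/ability correlation against the plant.
    """
    if truth_table is None:
        truth_table = truth_parameter_table(truth)
    common = [c for c in estimates.columns if c in truth_table.columns]
    if not common:
        raise ValueError("no overlapping parameters between truth and estimates")
    if estimates.shape[0] != truth_table.shape[0]:
        raise ValueError("subject sets differ between truth and estimates")
    rows = []
    for c in common:
        e = estimates[c].to_numpy(dtype=float)
        t = truth_table[c].to_numpy(dtype=float)
        err = e - t
        corr = np.corrcoef(t, e)[0, 1] if np.std(t) > 0 and np.std(e) > 0 else np.nan
        rows.append((c, float(err.mean()), float(np.sqrt(np.mean(err**2))), float(corr)))
    params = pd.DataFrame(rows, columns=["parameter", "bias", "rmse", "correlation"]).set_index(
        "parameter"
    )
    hit_rate = None
    if winning_specs is not None:
        key = truth.spec.key()
        hit_rate = float(np.mean([s.key() == key for s in winning_specs]))
    factor_err = None
    if recovered_factor_r is not None:
        factor_err = float(recovered_factor_r - truth.config.r_topdown_ability)
    return RecoveryReport(params, hit_rate, factor_err)


def truth_parameter_table(truth: GroundTruth) -> pd.DataFrame:
    """Planted parameter values in fit-label form (A and B entries)."""
    spec = truth.spec
    idx = {r: i for i, r in enumerate(spec.regions)}
    rows = []
    from .design import MOD_CHANNELS

    for p in truth.params:
        row = {}
        for a, b in spec.edges:
            row[f"A:{b}<-{a}"] = p.A[idx[b], idx[a]]
            row[f"A:{a}<-{b}"] = p.A[idx[a], idx[b]]
        for factor in MOD_CHANNELS:
            for src, dst in spec.modulation(factor):
                row[f"B:{factor}:{dst}<-{src}"] = p.B[factor][idx[dst], idx[src]]
        rows.append(row)
    return pd.DataFrame(rows)
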