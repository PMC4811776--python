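"""Candidate modulation structures, RFX Bayesian model selection, greedy search.

A :class:`ModelSpec` fixes the bidirectional connection graph, the
driving-input assignment (spatial stimuli -> SFS, verbal stimuli -> IFJ,
sub-task cues -> MFG) and, per experimental factor, which directed edges
it modulates.  Candidates vary only within anatomically motivated scopes:

* *Stimulus Domain*: the dorsal (SFS-cMFG) and ventral (IFJ-IFS) pathways
  with yoked directionality, optionally adding bidirectional lateral
  modulation (SFS-IFJ, IFS-cMFG),
* *Temporal Control*: the FPl-MFG connection,
* *Contextual Control*: contiguous edge groups — an upper section
  (FPl-MFG, FPl-IFS, FPl-cMFG, MFG-IFS, MFG-cMFG), a lower section
  (cMFG-SFS, IFS-IFJ), or both — crossed with direction; disjoint
  rostral+caudal scopes without mid-level edges are never produced.

Model comparison uses random-effects Bayesian model selection: a
variational Dirichlet posterior over model frequencies and Monte-Carlo
exceedance probabilities.  The greedy search optimizes one factor at a
time (Stimulus -> Temporal -> Contextual), assuming the winners found so
far, and cycles until a full pass changes nothing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma
from sklearn.base import BaseEstimator

from .design import MOD_CHANNELS
from .regions import DEFAULT_EDGES, REGIONS, ZONES

DEFAULT_DRIVE_TARGETS: tuple[tuple[str, str], ...] = (
    ("spatial", "SFS"),
    ("verbal", "IFJ"),
    ("cue", "MFG"),
)

FACTOR_STEPS = ("Stimulus", "Temporal", "Contextual")

_DIRECTIONS = ("none", "bu", "td", "bd")

# modulation pathways as (lower, upper) region pairs; "bu" = lower -> upper
SPATIAL_PATHWAY = ("SFS", "cMFG")
VERBAL_PATHWAY = ("IFJ", "IFS")
SPATIAL_LATERAL = ("SFS", "IFJ")
VERBAL_LATERAL = ("IFS", "cMFG")
TEMPORAL_PATHWAY = ("MFG", "FPl")
CONTEXT_UPPER = (("MFG", "FPl"), ("IFS", "FPl"), ("cMFG", "FPl"), ("IFS", "MFG"), ("cMFG", "MFG"))
CONTEXT_LOWER = (("SFS", "cMFG"), ("IFJ", "IFS"))
_CONTEXT_SCOPES = {"upper": CONTEXT_UPPER, "lower": CONTEXT_LOWER, "both": CONTEXT_UPPER + CONTEXT_LOWER}


def _directed(pair: tuple[str, str], direction: str) -> tuple[tuple[str, str], ...]:
    lower, upper = pair
    if direction == "none":
        return ()
    if direction == "bu":
        return ((lower, upper),)
    if direction == "td":
        return ((upper, lower),)
    if direction == "bd":
        return ((lower, upper), (upper, lower))
    raise ValueError(f"unknown direction {direction!r}")


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate structure: fixed edges, inputs, per-factor modulations."""

    regions: tuple[str, ...] = REGIONS
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES
    drive_targets: tuple[tuple[str, str], ...] = DEFAULT_DRIVE_TARGETS
    #: ordered (factor, directed (src, dst) edges) pairs
    modulations: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = ()

    def __post_init__(self) -> None:
        pairs = {_norm_pair(a, b) for a, b in self.edges}
        for factor, dedges in self.modulations:
            for src, dst in dedges:
                if _norm_pair(src, dst) not in pairs:
                    raise ValueError(
                        f"{factor} modulates {src}->{dst}, which is not a fixed connection"
                    )
        for _, region in self.drive_targets:
            if region not in self.regions:
                raise ValueError(f"driving input targets unknown region {region!r}")

    # -- accessors -------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def modulation(self, factor: str) -> tuple[tuple[str, str], ...]:
        for name, dedges in self.modulations:
            if name == factor:
                return dedges
        return ()

    def with_modulations(self, updates: dict[str, tuple[tuple[str, str], ...]]) -> "ModelSpec":
        current = {name: dedges for name, dedges in self.modulations}
        current.update(updates)
        ordered = tuple(
            (name, tuple(current[name])) for name in MOD_CHANNELS if current.get(name)
        )
        return replace(self, modulations=ordered)

    def key(self) -> str:
        """Canonical identity used for deduplication and caching."""
        mods = {f: sorted(self.modulation(f)) for f in MOD_CHANNELS if self.modulation(f)}
        return json.dumps(
            {
                "edges": sorted(map(list, map(sorted, self.edges))),
                "drives": sorted(map(list, self.drive_targets)),
                "mods": mods,
            },
            sort_keys=True,
        )

    # -- masks -----------------------------------------------------------
    def index(self, label: str) -> int:
        return self.regions.index(label)

    def a_mask(self) -> np.ndarray:
        n = self.n_regions
        mask = np.zeros((n, n), dtype=bool)
        for a, b in self.edges:
            mask[self.index(b), self.index(a)] = True
            mask[self.index(a), self.index(b)] = True
        return mask

    def b_mask(self, factor: str) -> np.ndarray:
        n = self.n_regions
        mask = np.zeros((n, n), dtype=bool)
        for src, dst in self.modulation(factor):
            mask[self.index(dst), self.index(src)] = True
        return mask

    def c_mask(self, drive_names: tuple[str, ...]) -> np.ndarray:
        mask = np.zeros((self.n_regions, len(drive_names)), dtype=bool)
        targets = dict(self.drive_targets)
        for k, name in enumerate(drive_names):
            if name in targets:
                mask[self.index(targets[name]), k] = True
        return mask

    def to_json(self) -> str:
        return json.dumps(
            {
                "regions": list(self.regions),
                "edges": [list(e) for e in self.edges],
                "drive_targets": [list(t) for t in self.drive_targets],
                "modulations": {f: [list(e) for e in d] for f, d in self.modulations},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        obj = json.loads(text)
        return cls(
            regions=tuple(obj["regions"]),
            edges=tuple(tuple(e) for e in obj["edges"]),
            drive_targets=tuple(tuple(t) for t in obj["drive_targets"]),
            modulations=tuple(
                (f, tuple(tuple(e) for e in d)) for f, d in obj["modulations"].items()
            ),
        )


def contextual_scope_is_contiguous(directed_edges) -> bool:
    """Check that a Contextual scope spans a contiguous rostral/caudal band.

    Edges are grouped into strata by zone: within-rostral (0), rostral-mid
    (1), mid-caudal (2).  A scope is contiguous when the strata it touches
    form an unbroken interval — e.g. rostral plus caudal edges without any
    mid-level edge are disjoint.
    """
    strata = set()
    for src, dst in directed_edges:
        za, zb = ZONES[src], ZONES[dst]
        zs = {za, zb}
        if zs == {"rostral"}:
            strata.add(0)
        elif zs == {"rostral", "mid"}:
            strata.add(1)
        elif zs == {"mid", "caudal"}:
            strata.add(2)
        else:  # within-mid / within-caudal dorsal-ventral pairs carry no band
            continue
    if not strata:
        return True
    return set(range(min(strata), max(strata) + 1)) <= strata


def enumerate_candidates(
    factor: str,
    current: ModelSpec,
    constraints: dict | None = None,
    examined: set[str] | None = None,
) -> list[ModelSpec]:
    """All specs varying only the given factor's assignment.

    ``factor`` is one of "Stimulus" (Spatial and Verbal yoked), "Temporal"
    or "Contextual".  ``constraints`` may restrict the option grids
    (keys: ``stimulus_directions``, ``stimulus_lateral``,
    ``temporal_directions``, ``contextual_options`` — the last a list of
    (scope, direction) pairs or "none").  ``examined`` drops specs whose
    key is already known.
    """
    cons = constraints or {}
    candidates: list[ModelSpec] = []
    if factor == "Stimulus":
        directions = cons.get("stimulus_directions", _DIRECTIONS)
        lateral_opts = cons.get("stimulus_lateral", (False, True))
        for direction, lateral in itertools.product(directions, lateral_opts):
            spatial = _directed(SPATIAL_PATHWAY, direction)
            verbal = _directed(VERBAL_PATHWAY, direction)
            if lateral:
                spatial = spatial + _directed(SPATIAL_LATERAL, "bd")
                verbal = verbal + _directed(VERBAL_LATERAL, "bd")
            candidates.append(current.with_modulations({"Spatial": spatial, "Verbal": verbal}))
    elif factor == "Temporal":
        directions = cons.get("temporal_directions", _DIRECTIONS)
        for direction in directions:
            candidates.append(
                current.with_modulations({"Temporal": _directed(TEMPORAL_PATHWAY, direction)})
            )
    elif factor == "Contextual":
        options = cons.get(
            "contextual_options",
            ("none",) + tuple(itertools.product(("upper", "lower", "both"), ("td", "bu", "bd"))),
        )
        for opt in options:
            if opt == "none":
                candidates.append(current.with_modulations({"Contextual": ()}))
                continue
            scope, direction = opt
            dedges: tuple[tuple[str, str], ...] = ()
            for pair in _CONTEXT_SCOPES[scope]:
                dedges = dedges + _directed(pair, direction)
            if not contextual_scope_is_contiguous(dedges):
                continue
            candidates.append(current.with_modulations({"Contextual": dedges}))
    else:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTOR_STEPS}")

    seen: set[str] = set(examined or ())
    out: list[ModelSpec] = []
    for cand in candidates:
        k = cand.key()
        if k in seen:
            continue
        seen.add(k)
        out.append(cand)
    return out


def default_winning_structure() -> ModelSpec:
    """The qualitative best-model structure used as the simulation default:
    bottom-up stimulus-domain modulations, top-down control modulations."""
    spec = ModelSpec()
    return spec.with_modulations(
        {
            "Spatial": _directed(SPATIAL_PATHWAY, "bu"),
            "Verbal": _directed(VERBAL_PATHWAY, "bu"),
            "Temporal": _directed(TEMPORAL_PATHWAY, "td"),
            "Contextual": tuple(
                d for pair in CONTEXT_UPPER for d in _directed(pair, "td")
            ),
        }
    )


# ----------------------------------------------------------------------
# Random-effects Bayesian model selection
# ----------------------------------------------------------------------


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies plus exceedance probabilities."""

    alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance: np.ndarray
    n_samples: int
    seed: int | None = None

    @property
    def best(self) -> int:
        return int(np.argmax(self.exceedance))


def rfx_bms(
    log_evidences: np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BMSResult:
    """Random-effects Bayesian model selection over subjects x models.

    Fits a variational Dirichlet posterior over population model
    frequencies (responsibilities proportional to exp(evidence + digamma
    terms), iterated to ``tol``) and estimates per-model exceedance
    probabilities — the probability that a model is more frequent than
    every competitor — by Monte Carlo over Dirichlet samples.
    """
    L = np.asarray(log_evidences, dtype=float)
    if L.ndim != 2:
        raise ValueError("log_evidences must be a subjects x models matrix")
    n_sub, n_mod = L.shape
    if n_mod < 2:
        raise ValueError("need at least 2 models")
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    bad = np.argwhere(~np.isfinite(L))
    if bad.size:
        s, m = bad[0]
        raise ValueError(f"non-finite log evidence for subject {s}, model {m}")

    alpha = np.full(n_mod, float(alpha0))
    for _ in range(max_iter):
        prev = alpha
        lnu = L + digamma(alpha)[None, :] - digamma(alpha.sum())
        lnu -= lnu.max(axis=1, keepdims=True)
        g = np.exp(lnu)
        g /= g.sum(axis=1, keepdims=True)
        alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha - prev)) < tol:
            break

    rng = np.random.default_rng(seed)
    counts = np.zeros(n_mod, dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        chunk = min(remaining, 20_000)
        draws = rng.dirichlet(alpha, size=chunk)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=n_mod)
        remaining -= chunk
    xp = counts / float(n_samples)
    return BMSResult(
        alpha=alpha,
        expected_frequency=alpha / alpha.sum(),
        exceedance=xp,
        n_samples=int(n_samples),
        seed=seed,
    )


# ----------------------------------------------------------------------
# Iterative greedy search
# ----------------------------------------------------------------------


@dataclass
class SearchIteration:
    cycle: int
    factor: str
    candidate_keys: list[str]
    exceedance: np.ndarray
    winner_key: str
    winner_exceedance: float
    changed: bool


@dataclass
class SearchTrace:
    iterations: list[SearchIteration] = field(default_factory=list)
    converged: bool = False
    n_models_examined: int = 0


class GreedyModelSearch(BaseEstimator):
    """Constrained iterative search over modulation structures.

    Per factor step every candidate is fitted to every subject, candidates
    are compared by RFX-BMS exceedance probability, and the winner is
    carried forward; the factor cycle repeats until one complete pass
    changes no assignment.  Per-subject evidences are cached by model key,
    and candidate fits warm-start from the incumbent model's posterior to
    keep the search tractable.

    Parameters
    ----------
    initial : ModelSpec
        Starting structure (typically no modulations).
    factor_order : tuple of str
        Visit order of factor steps; default Stimulus -> Temporal ->
        Contextual.
    constraints : dict, optional
        Candidate-grid restrictions forwarded to ``enumerate_candidates``.
    estimator_options : dict, optional
        Keyword arguments for the per-subject :class:`DCMEstimator`.
    alpha0, n_bms_samples : float, int
        RFX-BMS Dirichlet prior and Monte-Carlo sample count.
    max_cycles : int
        Search is flagged non-converged beyond this many factor cycles.
    """

    def __init__(
        self,
        initial: ModelSpec | None = None,
        factor_order: tuple[str, ...] = FACTOR_STEPS,
        constraints: dict | None = None,
        estimator_options: dict | None = None,
        alpha0: float = 1.0,
        n_bms_samples: int = 100_000,
        max_cycles: int = 10,
        seed: int = 0,
        verbose: bool = False,
    ) -> None:
        self.initial = initial
        self.factor_order = factor_order
        self.constraints = constraints
        self.estimator_options = estimator_options
        self.alpha0 = alpha0
        self.n_bms_samples = n_bms_samples
        self.max_cycles = max_cycles
        self.seed = seed
        self.verbose = verbose

    def fit(self, datasets, timelines):
        """Run the search on a cohort.

        ``datasets`` is a sequence of per-subject ROI time series (or
        arrays); ``timelines`` is one shared InputTimeline or a sequence of
        per-subject timelines.
        """
        from .estimate import DCMEstimator  # local import to avoid a cycle

        if not isinstance(timelines, (list, tuple)):
            timelines = [timelines] * len(datasets)
        if len(timelines) != len(datasets):
            raise ValueError("one timeline (or one per subject) is required")
        n_sub = len(datasets)
        current = self.initial if self.initial is not None else ModelSpec()
        opts = dict(self.estimator_options or {})
        rng_seed = int(self.seed)

        # cache: model key -> (evidences[n_sub], [theta/labels per subject])
        cache: dict[str, tuple[np.ndarray, list]] = {}
        trace = SearchTrace()

        def evidences_for(spec: ModelSpec, warm: list | None):
            k = spec.key()
            if k in cache:
                return cache[k]
            ev = np.empty(n_sub)
            fits = []
            for s in range(n_sub):
                est = DCMEstimator(spec=spec, seed=rng_seed + 1009 * s, **opts)
                init = None
                if warm is not None and warm[s] is not None:
                    init = warm[s]
                est.fit(datasets[s], timelines[s], warm_start=init)
                ev[s] = est.log_evidence_
                fits.append((est.labels_, est.theta_))
            cache[k] = (ev, fits)
            return cache[k]

        warm_fits: list | None = None
        bms_round = 0
        for cycle in range(self.max_cycles):
            changed_any = False
            for factor in self.factor_order:
                cands = enumerate_candidates(factor, current, self.constraints)
                keys = [c.key() for c in cands]
                ev_matrix = np.empty((n_sub, len(cands)))
                for j, cand in enumerate(cands):
                    ev, _ = evidences_for(cand, warm_fits)
                    ev_matrix[:, j] = ev
                if len(cands) == 1:
                    xp = np.array([1.0])
                else:
                    bms_round += 1
                    res = rfx_bms(
                        ev_matrix,
                        alpha0=self.alpha0,
                        n_samples=self.n_bms_samples,
                        seed=rng_seed + 7919 * bms_round,
                    )
                    xp = res.exceedance
                win = int(np.argmax(xp))
                winner = cands[win]
                changed = winner.key() != current.key()
                trace.iterations.append(
                    SearchIteration(cycle, factor, keys, xp, winner.key(), float(xp[win]), changed)
                )
                if self.verbose:
                    print(f"[cycle {cycle}] {factor}: xp={np.round(xp, 3)} -> {'new' if changed else 'kept'}")
                current = winner
                warm_fits = cache[current.key()][1]
                changed_any = changed_any or changed
            if not changed_any:
                trace.converged = True
                break
        trace.n_models_examined = len(cache)
        self.best_spec_ = current
        self.trace_ = trace
        self.evidence_cache_ = {k: v[0] for k, v in cache.items()}
        if not trace.converged:
            import warnings

            warnings.warn("greedy model search did not converge within max_cycles", RuntimeWarning)
        return self


def greedy_search(datasets, timelines, initial: ModelSpec | None = None, config: dict | None = None) -> SearchTrace:
    """Functional wrapper over :class:`GreedyModelSearch`; returns the trace
    with the winning spec attached as ``trace.winner``."""
    search = GreedyModelSearch(initial=initial, **(config or {}))
    search.fit(datasets, timelines)
    trace = search.trace_
    trace.winner = search.best_spec_  # type: ignore[attr-defined]
    return trace
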