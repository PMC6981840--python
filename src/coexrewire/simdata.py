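"""Synthetic blood-microarray data with planted, fully known structure.

The generator emulates what the downstream pipeline expects from an
RMA-normalised expression study: a probes x samples log2-intensity matrix,
a per-subject dated diagnosis table (NC / MCI / AD), and a serialized ground
truth enumerating exactly what was planted — differentially expressed probes,
per-state correlated probe blocks, the consensus gained/lost edges they imply
relative to the reference state, and the most-rewired node(s).

Within each state, samples are drawn from a multivariate Gaussian in log2
space whose correlation matrix is assembled from the configured blocks.  For
a single equicorrelated block this is exactly the one-factor model
``x = sqrt(r) * f + sqrt(1 - r) * eps``; sampling through the Cholesky factor
of the full target matrix generalises it to negative pair targets and to
cross-block targets while keeping every pairwise correlation analytically
known, which is what makes recovery testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LOG2, STATES, ExpressionMatrix

__all__ = [
    "BlockSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_null",
    "write_fixture",
    "read_fixture",
    "rewiring_scenario",
    "consensus_scenario",
]


@dataclass(frozen=True)
class BlockSpec:
    """A set of probes sharing a common pairwise correlation, per state.

    ``targets`` maps a state label to the within-block pairwise Pearson r
    planted in that state; states not listed get r = 0 for those pairs.
    """

    probes: tuple[str, ...]
    targets: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("block probe set contains duplicates")
        for state, r in self.targets.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"block target for {state} outside [-1, 1]: {r}")
            k = len(self.probes)
            if r < 0 and k > 2 and r < -1.0 / (k - 1):
                raise ValueError(
                    f"uniform target {r} for a {k}-probe block is below the "
                    f"equicorrelation bound -1/(k-1) = {-1.0 / (k - 1):.4f}"
                )


@dataclass(frozen=True)
class CrossSpec:
    """Pairwise correlation planted between two disjoint probe sets."""

    probes_a: tuple[str, ...]
    probes_b: tuple[str, ...]
    targets: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.probes_a) & set(self.probes_b):
            raise ValueError("cross-target probe sets must be disjoint")
        for state, r in self.targets.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"cross target for {state} outside [-1, 1]: {r}")


@dataclass
class SimConfig:
    n_probes: int = 50
    n_per_state: int = 100
    states: tuple[str, ...] = STATES
    #: (probe, state, log2 shift) triples: additive shift of that probe's mean
    de_probes: list[tuple[str, str, float]] = field(default_factory=list)
    blocks: list[BlockSpec] = field(default_factory=list)
    cross_targets: list[CrossSpec] = field(default_factory=list)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0
    #: strict |r| threshold at which planted correlations count as true edges
    truth_threshold: float = 0.1
    sample_date: str = "2010-06-15"
    #: extra diagnosis records per subject at these day offsets (decoy labels)
    decoy_offsets_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_per_state <= 0:
            raise ValueError("counts must be positive")
        if self.n_per_state < 3:
            raise ValueError("n_per_state must be >= 3 (correlation undefined below)")
        if self.baseline_log2_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("scale parameters must be > 0")
        universe = set(self.probe_ids())
        for blk in self.blocks:
            unknown = set(blk.probes) - universe
            if unknown:
                raise ValueError(f"block probes outside the universe: {sorted(unknown)}")
        for xs in self.cross_targets:
            unknown = (set(xs.probes_a) | set(xs.probes_b)) - universe
            if unknown:
                raise ValueError(f"cross-target probes outside the universe: {sorted(unknown)}")
        for probe, state, _ in self.de_probes:
            if probe not in universe:
                raise ValueError(f"DE probe outside the universe: {probe}")
            if state not in self.states:
                raise ValueError(f"DE state unknown: {state}")

    def probe_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_probes)]


@dataclass
class GroundTruth:
    """Exactly the structure a SimConfig plants, in downstream terms."""

    de_probes: list[tuple[str, str, float]]
    #: state -> list of (probe_a, probe_b, planted r), a < b, nonzero r only
    edges_by_state: dict[str, list[tuple[str, str, float]]]
    #: consensus vs the first (reference) state, at truth_threshold, per sign
    consensus_gained: list[tuple[str, str, str]]  # (a, b, sign)
    consensus_lost: list[tuple[str, str, str]]
    rewired_nodes: list[str]

    def to_json_dict(self) -> dict:
        return {
            "de_probes": [list(t) for t in self.de_probes],
            "edges_by_state": {
                s: [list(e) for e in edges] for s, edges in self.edges_by_state.items()
            },
            "consensus_gained": [list(e) for e in self.consensus_gained],
            "consensus_lost": [list(e) for e in self.consensus_lost],
            "rewired_nodes": list(self.rewired_nodes),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_probes=[(p, s, float(x)) for p, s, x in d["de_probes"]],
            edges_by_state={
                s: [(a, b, float(r)) for a, b, r in edges]
                for s, edges in d["edges_by_state"].items()
            },
            consensus_gained=[tuple(e) for e in d["consensus_gained"]],
            consensus_lost=[tuple(e) for e in d["consensus_lost"]],
            rewired_nodes=list(d["rewired_nodes"]),
        )


def _target_matrix(config: SimConfig, state: str) -> np.ndarray:
    """Assemble the planted correlation matrix for one state."""
    probes = config.probe_ids()
    idx = {p: i for i, p in enumerate(probes)}
    sigma = np.eye(config.n_probes)
    assigned: dict[tuple[int, int], float] = {}

    def put(i: int, j: int, r: float) -> None:
        key = (min(i, j), max(i, j))
        if key in assigned and assigned[key] != r:
            raise ValueError(
                f"conflicting correlation targets for pair {probes[key[0]]},{probes[key[1]]} "
                f"in state {state}: {assigned[key]} vs {r}"
            )
        assigned[key] = r
        sigma[i, j] = sigma[j, i] = r

    for blk in config.blocks:
        r = blk.targets.get(state, 0.0)
        if r == 0.0:
            continue
        members = [idx[p] for p in blk.probes]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                put(members[a], members[b], r)
    for xs in config.cross_targets:
        r = xs.targets.get(state, 0.0)
        if r == 0.0:
            continue
        for pa in xs.probes_a:
            for pb in xs.probes_b:
                put(idx[pa], idx[pb], r)
    return sigma


def _planted_edges(config: SimConfig) -> dict[str, list[tuple[str, str, float]]]:
    probes = config.probe_ids()
    out: dict[str, list[tuple[str, str, float]]] = {}
    for state in config.states:
        sigma = _target_matrix(config, state)
        edges = []
        n = len(probes)
        for i in range(n):
            for j in range(i + 1, n):
                if sigma[i, j] != 0.0:
                    edges.append((probes[i], probes[j], float(sigma[i, j])))
        out[state] = edges
    return out


def _sign_edge_sets(
    edges_by_state: dict[str, list[tuple[str, str, float]]], threshold: float
) -> dict[str, dict[str, set[tuple[str, str]]]]:
    """Per sign class, the per-state edge sets implied at a strict threshold."""
    out: dict[str, dict[str, set[tuple[str, str]]]] = {"positive": {}, "negative": {}}
    for state, edges in edges_by_state.items():
        out["positive"][state] = {(a, b) for a, b, r in edges if r > threshold}
        out["negative"][state] = {(a, b) for a, b, r in edges if r < -threshold}
    return out


def _ground_truth(config: SimConfig) -> GroundTruth:
    edges_by_state = _planted_edges(config)
    states = list(config.states)
    ref, conditions = states[0], states[1:]
    by_sign = _sign_edge_sets(edges_by_state, config.truth_threshold)

    gained: list[tuple[str, str, str]] = []
    lost: list[tuple[str, str, str]] = []
    for sign, per_state in by_sign.items():
        ref_set = per_state[ref]
        cond_sets = [per_state[c] for c in conditions]
        if cond_sets:
            in_all = set.intersection(*cond_sets)
            in_none_union = set.union(*cond_sets) if cond_sets else set()
            gained += [(a, b, sign) for a, b in sorted(in_all - ref_set)]
            lost += [(a, b, sign) for a, b in sorted(ref_set - in_none_union)]

    # rewired nodes: per (neighbour, sign) slot, does presence vary over states?
    changes: dict[str, int] = {p: 0 for p in config.probe_ids()}
    for sign, per_state in by_sign.items():
        all_pairs = set.union(*per_state.values()) if per_state else set()
        for a, b in all_pairs:
            presence = [(a, b) in per_state[s] for s in states]
            if any(presence) and not all(presence):
                changes[a] += 1
                changes[b] += 1
    top = max(changes.values()) if changes else 0
    rewired = sorted(p for p, c in changes.items() if c == top and top > 0)

    return GroundTruth(
        de_probes=list(config.de_probes),
        edges_by_state=edges_by_state,
        consensus_gained=gained,
        consensus_lost=lost,
        rewired_nodes=rewired,
    )


def simulate_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw a synthetic study: log2 expression, diagnosis table, ground truth.

    Returns
    -------
    matrix : ExpressionMatrix (scale ``log2``)
    diagnoses : DataFrame with columns ``SubjectID, ExamDate, Diagnosis``
    truth : GroundTruth

    The same config (including seed) is bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    probes = config.probe_ids()
    n = config.n_probes

    # probe-level baseline abundance, shared across states
    mu = config.baseline_log2_mean + config.baseline_log2_sd * rng.standard_normal(n)

    shift = np.zeros((n, len(config.states)))
    p_idx = {p: i for i, p in enumerate(probes)}
    s_idx = {s: i for i, s in enumerate(config.states)}
    for probe, state, delta in config.de_probes:
        shift[p_idx[probe], s_idx[state]] += delta

    chol = {}
    for state in config.states:
        sigma = _target_matrix(config, state)
        try:
            chol[state] = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"planted correlation targets for state {state} do not form a "
                "positive-definite matrix; weaken block/cross targets"
            ) from exc

    base = date.fromisoformat(config.sample_date)
    cols: list[str] = []
    blocks_vals: list[np.ndarray] = []
    diag_rows: list[tuple[str, str, str]] = []
    other = {s: [t for t in config.states if t != s] for s in config.states}
    subj = 0
    for state in config.states:
        z = rng.standard_normal((n, config.n_per_state))
        vals = (
            mu[:, None]
            + shift[:, [s_idx[state]]]
            + config.noise_sd * (chol[state] @ z)
        )
        blocks_vals.append(vals)
        for _ in range(config.n_per_state):
            sid = f"SUBJ{subj:04d}"
            subj += 1
            cols.append(f"{sid}_{base.strftime('%Y%m%d')}")
            diag_rows.append((sid, base.isoformat(), state))
            for k, off in enumerate(config.decoy_offsets_days):
                pool = other[state] or [state]
                decoy_label = pool[k % len(pool)]
                decoy_date = (base + timedelta(days=off)).isoformat()
                diag_rows.append((sid, decoy_date, decoy_label))

    values = pd.DataFrame(np.hstack(blocks_vals), index=probes, columns=cols)
    matrix = ExpressionMatrix(values, scale=LOG2)
    diagnoses = pd.DataFrame(diag_rows, columns=["SubjectID", "ExamDate", "Diagnosis"])
    return matrix, diagnoses, _ground_truth(config)


def simulate_null(
    n_probes: int, n_per_state: int, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """All probes i.i.d. across samples and states; no planted structure."""
    config = SimConfig(n_probes=n_probes, n_per_state=n_per_state, seed=seed)
    matrix, diagnoses, _ = simulate_expression(config)
    return matrix, diagnoses


# ---------------------------------------------------------------------------
# canonical recovery scenarios


def rewiring_scenario(
    seed: int,
    n_probes: int = 30,
    n_per_state: int = 150,
    block_r: float = 0.8,
    partners_per_state: int = 8,
) -> SimConfig:
    """One hub probe whose correlation partners switch completely per state.

    The hub P0000 is planted in a different equicorrelated block in each
    state (disjoint partner sets), so every one of its true edges is added
    or removed between any two states — the strongest possible rewiring
    signal — while its partners rewire far less.
    """
    probes = [f"P{i:04d}" for i in range(n_probes)]
    need = 1 + partners_per_state * len(STATES)
    if need > n_probes:
        raise ValueError(f"need at least {need} probes for this scenario")
    hub = probes[0]
    blocks = []
    for k, state in enumerate(STATES):
        partners = probes[1 + k * partners_per_state : 1 + (k + 1) * partners_per_state]
        blocks.append(BlockSpec(probes=(hub, *partners), targets={state: block_r}))
    return SimConfig(
        n_probes=n_probes, n_per_state=n_per_state, blocks=blocks, seed=seed
    )


def consensus_scenario(
    seed: int,
    n_probes: int = 30,
    n_per_state: int = 150,
    block_r: float = 0.8,
    absent_r: float = -0.05,
    cross_r: float = -0.10,
) -> SimConfig:
    """Two modules that swap co-expression between NC and the conditions.

    Module L (half the probes) is tightly co-expressed in NC and collapses
    to mild anti-correlation in MCI and AD: its internal edges are the
    planted consensus-lost set.  Module G mirrors this (co-expressed only in
    the conditions): its internal edges are the planted consensus-gained
    set.  Cross-module pairs carry a mild negative correlation in every
    state so that no pair sits exactly at the null, where edge
    presence/absence at a low threshold is a coin toss rather than a
    recoverable signal.
    """
    probes = [f"P{i:04d}" for i in range(n_probes)]
    half = n_probes // 2
    mod_l, mod_g = tuple(probes[:half]), tuple(probes[half:])
    conditions = [s for s in STATES if s != STATES[0]]
    blocks = [
        BlockSpec(probes=mod_l, targets={STATES[0]: block_r, **{c: absent_r for c in conditions}}),
        BlockSpec(probes=mod_g, targets={STATES[0]: absent_r, **{c: block_r for c in conditions}}),
    ]
    cross = [CrossSpec(probes_a=mod_l, probes_b=mod_g, targets={s: cross_r for s in STATES})]
    return SimConfig(
        n_probes=n_probes,
        n_per_state=n_per_state,
        blocks=blocks,
        cross_targets=cross,
        seed=seed,
    )


def demo_scenario(seed: int, n_probes: int = 50, n_per_state: int = 60) -> SimConfig:
    """A small end-to-end fixture exercising every pipeline stage.

    Twenty probes carry group mean shifts (ten up-, ten down-regulated in the
    conditions) so the ANOVA stage has signal; one block is co-expressed only
    in NC (consensus-lost edges) and one only in MCI/AD (consensus-gained
    edges).  ``noise_sd`` is set so linear-scale CVs fall inside the default
    [0.7, 10] filter window, as they do for expressed blood probes.
    """
    probes = [f"P{i:04d}" for i in range(n_probes)]
    if n_probes < 20:
        raise ValueError("demo scenario needs at least 20 probes")
    de: list[tuple[str, str, float]] = []
    for p in probes[:10]:
        de += [(p, "MCI", 0.6), (p, "AD", 1.0)]
    for p in probes[10:20]:
        de += [(p, "MCI", -0.6), (p, "AD", -1.0)]
    blocks = [
        BlockSpec(probes=tuple(probes[0:6]), targets={"NC": 0.7}),
        BlockSpec(probes=tuple(probes[6:12]), targets={"MCI": 0.7, "AD": 0.7}),
    ]
    return SimConfig(
        n_probes=n_probes,
        n_per_state=n_per_state,
        de_probes=de,
        blocks=blocks,
        noise_sd=1.0,
        seed=seed,
    )


def score_consensus_recovery(
    truth: GroundTruth,
    predicted_gained: set[tuple[str, str]],
    predicted_lost: set[tuple[str, str]],
    sign: str = "positive",
) -> tuple[float, float]:
    """Precision and recall of predicted consensus edges for one sign class.

    Gained and lost predictions are pooled (kept distinct as categories) and
    compared against the planted consensus sets of the same sign.
    """
    pred = {("gained", *sorted(e)) for e in predicted_gained}
    pred |= {("lost", *sorted(e)) for e in predicted_lost}
    true = {("gained", u, v) for u, v, s in truth.consensus_gained if s == sign}
    true |= {("lost", u, v) for u, v, s in truth.consensus_lost if s == sign}
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(true) if true else 1.0
    return precision, recall


SCENARIOS = {
    "demo": demo_scenario,
    "rewiring": rewiring_scenario,
    "consensus": consensus_scenario,
}


# ---------------------------------------------------------------------------
# fixture I/O

EXPRESSION_CSV = "expression.csv"
DIAGNOSIS_CSV = "diagnosis.csv"
TRUTH_JSON = "ground_truth.json"


def write_fixture(
    directory, matrix: ExpressionMatrix, diagnoses: pd.DataFrame, truth: GroundTruth | None
) -> dict[str, Path]:
    """Write expression CSV, diagnosis CSV and ground-truth JSON.

    The expression CSV has a ``ProbeSetID`` first column and one column per
    sample; values round-trip exactly (full float repr).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / EXPRESSION_CSV,
        "diagnosis": directory / DIAGNOSIS_CSV,
    }
    try:
        matrix.values.to_csv(paths["expression"], index_label="ProbeSetID")
        diagnoses.to_csv(paths["diagnosis"], index=False)
        if truth is not None:
            paths["truth"] = directory / TRUTH_JSON
            paths["truth"].write_text(json.dumps(truth.to_json_dict(), indent=1))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths


def read_fixture(directory) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth | None]:
    """Read back what :func:`write_fixture` wrote."""
    directory = Path(directory)
    values = pd.read_csv(directory / EXPRESSION_CSV, index_col="ProbeSetID")
    values.index.name = None
    matrix = ExpressionMatrix(values, scale=LOG2)
    diagnoses = pd.read_csv(directory / DIAGNOSIS_CSV, dtype=str)
    truth = None
    truth_path = directory / TRUTH_JSON
    if truth_path.exists():
        truth = GroundTruth.from_json_dict(json.loads(truth_path.read_text()))
    return matrix, diagnoses, truth
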