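"""Synthetic cohort generation with known ground truth.

Every downstream stage of the redundancy pipeline is testable without any
imaging data: this module generates regional BOLD-like timeseries whose
windows alternate between a *redundant* and a *fragile* latent covariance
state, cognitive test batteries driven by three latent domain factors, and
moderated outcome variables with known regression coefficients.

Redundant state
    Two equally sized region communities, each driven by a single shared
    latent factor (within-community correlation ``snr / (snr + 1)``), plus a
    weak homotopic-style coupling pairing each region with one partner in
    the opposite community.  Under proportional thresholding the tied
    within-community edges fill the density grid up to ~50%; the first grid
    density whose edge quota exceeds the within-community edge count pulls
    in several vertex-disjoint cross edges at once, so the network becomes
    two-connected at the very density at which it first becomes
    one-connected.  The homotopic matching biases the strongest cross edges
    toward vertex-disjoint pairs, preventing occasional cut-vertex "hubs"
    caused by shared factor-sampling noise.

Fragile state
    A random spanning tree with maximum degree 3, each edge carrying its
    own latent factor.  The network becomes one-connected once the tree
    edges are in, but leaves acquire second pathways only through weak
    noise edges at much higher densities, so two-connectedness lags.

Both constructions are exact factor models (covariance ``B Bᵀ + D``), hence
positive semi-definite by construction, and fully reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dynfc import RegionalTimeseries

REDUNDANT = "REDUNDANT"
FRAGILE = "FRAGILE"

#: Variance of the homotopic cross-community coupling in the redundant
#: state, relative to unit community-factor variance.  Strong enough to
#: bias the first cross edges toward vertex-disjoint partner pairs, weak
#: enough to stay far below the within-community correlation tier.
HOMOTOPIC_VAR = 0.25

#: Degree cap for the fragile-state spanning tree; keeps every tree-edge
#: correlation at least 1/(cap * (1 + 1/snr)), well above background.
TREE_DEGREE_CAP = 3

#: Standardized factor loadings of the default cognitive battery
#: (tests x [episodic, semantic, executive]).  The structure emulates what
#: large lifespan batteries show: a dominant episodic/general dimension
#: that executive speed tests also load on (positive manifold), a partly
#: separate crystallized/semantic dimension with a slight negative tilt on
#: the first, and a Trail Making test that is nearly unique (its variance
#: surfaces as its own minor component).  Unique variances rise from 0.15
#: (best episodic test) to 0.98 (Trail Making), which gives the z-scored
#: battery a graded scree — roughly 40/16/8% for the first three
#: components with a gently declining tail — so the line-distance elbow
#: rule lands on three components.
_EPI_UNIQUE = np.linspace(0.15, 0.40, 6)
_SEM_UNIQUE = np.array([0.30, 0.36, 0.42])
_EXEC_UNIQUE = np.array([0.68, 0.74, 0.80])


def _standardized_loadings() -> tuple[np.ndarray, np.ndarray]:
    L = np.zeros((13, 3))
    L[:6, 0] = np.sqrt(1.0 - _EPI_UNIQUE)
    L[6:9, 0] = -0.18
    L[6:9, 1] = np.sqrt(1.0 - _SEM_UNIQUE - 0.18**2)
    L[9, 0] = -0.10  # trail making: almost pure unique variance
    L[9, 2] = -0.10
    L[10:13, 0] = 0.35
    L[10:13, 2] = np.sqrt(1.0 - _EXEC_UNIQUE - 0.35**2)
    unique = 1.0 - (L**2).sum(axis=1)
    return L, unique


DEFAULT_FACTOR_SD = (2.0, 1.3, 1.0)
DEFAULT_COG_NOISE_SD = 0.3


def default_cognitive_loadings(
    factor_sd=DEFAULT_FACTOR_SD, noise_sd: float = DEFAULT_COG_NOISE_SD
) -> np.ndarray:
    """Raw-score loading matrix realizing the standardized battery design.

    Raw test scales are chosen so that with factors of SD ``factor_sd`` and
    i.i.d. noise of SD ``noise_sd``, z-scored scores have exactly the
    standardized loading structure and unique variances described above.
    """
    L, unique = _standardized_loadings()
    scale = noise_sd / np.sqrt(unique)  # per-test raw scale
    return L * scale[:, None] / np.asarray(factor_sd, dtype=float)[None, :]


#: The 13-test cognitive battery, in the order used throughout.
COGNITIVE_TESTS = (
    "vpa_immediate_recall",
    "vpa_delayed_recall",
    "vpa_delayed_free_recall",
    "associative_recall",
    "nih_auditory_verbal_learning",
    "nih_picture_sequence_memory",
    "shipley_vocabulary",
    "nih_picture_vocabulary",
    "nih_oral_reading_recognition",
    "trail_making_task",
    "nih_flanker",
    "nih_dimensional_card_sort",
    "nih_list_sort_working_memory",
)

#: Which cognitive domain each test belongs to (6 episodic, 3 semantic,
#: 4 executive).
TEST_CATEGORIES: Mapping[str, str] = {
    **{t: "episodic" for t in COGNITIVE_TESTS[:6]},
    **{t: "semantic" for t in COGNITIVE_TESTS[6:9]},
    **{t: "executive" for t in COGNITIVE_TESTS[9:]},
}


@dataclass(frozen=True)
class StateSequence:
    """Ground-truth latent state per generation block.

    Blocks are contiguous, equal-length stretches of volumes; all windows
    fully inside a block inherit its label as ground truth.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("state sequence must not be empty")
        bad = set(self.labels) - {REDUNDANT, FRAGILE}
        if bad:
            raise ValueError(f"unknown state tags: {sorted(bad)}")

    @property
    def n_blocks(self) -> int:
        return len(self.labels)

    @classmethod
    def constant(cls, state: str, n_blocks: int = 1) -> "StateSequence":
        return cls(tuple([state] * n_blocks))


@dataclass(frozen=True)
class CohortTruth:
    """Generator parameters sufficient to recompute every expected effect."""

    seed: int
    betas: tuple[float, ...]
    noise_sd: float
    loadings: np.ndarray
    factor_sd: tuple[float, ...]
    cog_noise_sd: float
    snr: float
    state_sequences: Mapping[tuple[str, str], StateSequence]
    bfr_true: Mapping[str, float]


@dataclass(frozen=True)
class SyntheticCohort:
    """A full synthetic study: timeseries, subject table, cognition, truth."""

    timeseries: Mapping[tuple[str, str], RegionalTimeseries]
    subjects: pd.DataFrame
    cognitive_scores: pd.DataFrame
    truth: CohortTruth

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.subjects["subject_id"])

    @property
    def session_ids(self) -> tuple[str, ...]:
        return tuple(sorted({k[1] for k in self.timeseries}))


def _redundant_loadings(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Factor loading matrix of the two-community redundant design."""
    a = n_regions // 2
    b = n_regions - a
    n_pairs = min(a, b)
    B = np.zeros((n_regions, 2 + n_pairs))
    B[:a, 0] = 1.0
    B[a:, 1] = 1.0
    partners = rng.permutation(a)  # random homotopic partner assignment
    for k in range(n_pairs):
        B[partners[k], 2 + k] = np.sqrt(HOMOTOPIC_VAR)
        B[a + k, 2 + k] = np.sqrt(HOMOTOPIC_VAR)
    return B


def _fragile_loadings(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Edge-factor loadings of a degree-capped random spanning tree."""
    order = rng.permutation(n_regions)
    g = nx.Graph()
    g.add_node(int(order[0]))
    for i in range(1, n_regions):
        candidates = sorted(v for v in g.nodes if g.degree(v) < TREE_DEGREE_CAP)
        parent = int(rng.choice(candidates))
        g.add_edge(int(order[i]), parent)
    edges = sorted(g.edges)
    B = np.zeros((n_regions, len(edges)))
    for e, (u, v) in enumerate(edges):
        B[u, e] = 1.0
        B[v, e] = 1.0
    return B


def gen_timeseries(
    n_regions: int,
    n_volumes: int,
    state_seq: StateSequence,
    snr: float = 10.0,
    seed: int = 0,
    tr_seconds: float = 3.0,
    subject_id: str = "sub-01",
    session_id: str = "ses-01",
) -> RegionalTimeseries:
    """Sample a regional timeseries alternating between latent states.

    ``n_volumes`` is split into ``state_seq.n_blocks`` equal blocks; each
    block is drawn i.i.d. from its state's factor-model covariance
    (``B Bᵀ + diag(struct_var / snr)``).  Identical arguments and seed give
    bit-identical output.  Designed for ``n_regions >= 12``; below that the
    redundant state's density-grid arithmetic loses its safety margin.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    if n_volumes < state_seq.n_blocks:
        raise ValueError("need at least one volume per state block")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    # fixed per-state designs so that same-state blocks share structure
    designs = {
        REDUNDANT: _redundant_loadings(n_regions, rng),
        FRAGILE: _fragile_loadings(n_regions, rng),
    }
    noise_sd = {
        s: np.sqrt((B**2).sum(axis=1) / snr) for s, B in designs.items()
    }
    block_len = n_volumes // state_seq.n_blocks
    lengths = [block_len] * state_seq.n_blocks
    lengths[-1] += n_volumes - block_len * state_seq.n_blocks
    chunks = []
    for label, t in zip(state_seq.labels, lengths):
        B = designs[label]
        Z = rng.standard_normal((t, B.shape[1]))
        eps = rng.standard_normal((t, n_regions)) * noise_sd[label]
        chunks.append(Z @ B.T + eps)
    return RegionalTimeseries(
        values=np.vstack(chunks),
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        session_id=session_id,
    )


def block_loadings(
    sizes: Sequence[int] = (6, 3, 4), magnitude: float = 1.0
) -> np.ndarray:
    """Block-diagonal test-on-factor loading matrix (tests x factors)."""
    n_tests = sum(sizes)
    L = np.zeros((n_tests, len(sizes)))
    row = 0
    for col, s in enumerate(sizes):
        L[row : row + s, col] = magnitude
        row += s
    return L


def gen_cognitive_scores(
    n_subjects: int,
    loadings: np.ndarray | None = None,
    factor_sd: Sequence[float] = DEFAULT_FACTOR_SD,
    noise_sd: float = DEFAULT_COG_NOISE_SD,
    seed: int = 0,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cognitive test scores from latent domain factors.

    ``scores = factors @ loadings.T + noise``.  The default 13 x 3 loading
    matrix realizes the standardized battery structure of
    :func:`default_cognitive_loadings` (episodic/semantic/executive factors
    with a positive manifold and a near-unique Trail Making test), so the
    downstream z-score + PCA + elbow stage retains three components.  Pass
    ``factors`` (subjects x n_factors) to supply externally generated
    factor values (e.g. an episodic factor built from a moderation model).
    """
    if loadings is None:
        loadings = default_cognitive_loadings(factor_sd, noise_sd)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[0] != len(COGNITIVE_TESTS):
        raise ValueError(
            f"loadings must have {len(COGNITIVE_TESTS)} rows, got {loadings.shape[0]}"
        )
    factor_sd = np.asarray(factor_sd, dtype=float)
    if loadings.shape[1] != factor_sd.size:
        raise ValueError("loadings columns must match factor_sd length")
    if np.any(factor_sd <= 0):
        raise ValueError("factor_sd must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if factors is None:
        factors = rng.standard_normal((n_subjects, factor_sd.size)) * factor_sd
    else:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (n_subjects, loadings.shape[1]):
            raise ValueError("factors shape must be (n_subjects, n_factors)")
    scores = factors @ loadings.T + noise_sd * rng.standard_normal(
        (n_subjects, loadings.shape[0])
    )
    return pd.DataFrame(scores, columns=list(COGNITIVE_TESTS))


def gen_moderated_outcome(
    bc: np.ndarray,
    bfr: np.ndarray,
    site: np.ndarray,
    sex: np.ndarray,
    betas: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Outcome from the moderation model with known coefficients.

    ``betas = (b_bc, b_bfr, b_interaction, b_site, b_sex, intercept)``;
    the outcome is ``intercept + b_bc*bc + b_bfr*bfr + b_int*bc*bfr +
    b_site*site + b_sex*sex + noise``.
    """
    bc, bfr, site, sex = (np.asarray(x, dtype=float) for x in (bc, bfr, site, sex))
    n = bc.shape[0]
    for name, v in (("bfr", bfr), ("site", site), ("sex", sex)):
        if v.shape[0] != n:
            raise ValueError(f"{name} length {v.shape[0]} != bc length {n}")
    if len(betas) != 6:
        raise ValueError("betas must be (b_bc, b_bfr, b_int, b_site, b_sex, intercept)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    b_bc, b_bfr, b_int, b_site, b_sex, intercept = betas
    rng = np.random.default_rng(seed)
    return (
        intercept
        + b_bc * bc
        + b_bfr * bfr
        + b_int * bc * bfr
        + b_site * site
        + b_sex * sex
        + noise_sd * rng.standard_normal(n)
    )


def gen_subject_table(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Demographics and brain-change measures for a synthetic cohort.

    Age is uniform over 18-89 years; cortical thickness (mm), cortical GM
    volume (mm^3) and brain age (years) are linear in age plus noise; total
    intracranial volume is age-independent; maximum head displacement is
    right-skewed (log-normal) so a motion cut at 2.5 mm excludes a small
    fraction of subjects.  Sex and site are 0/1 codes.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    age = rng.uniform(18.0, 89.0, n_subjects)
    sex = rng.integers(0, 2, n_subjects)
    site = rng.integers(0, 2, n_subjects)
    thickness = 2.75 - 0.006 * (age - 18.0) + rng.normal(0.0, 0.07, n_subjects)
    tiv = rng.normal(1_450_000.0, 110_000.0, n_subjects)
    gm_frac = 0.42 - 0.0012 * (age - 18.0) + rng.normal(0.0, 0.012, n_subjects)
    gm_volume = gm_frac * tiv
    brain_age = age + rng.normal(0.0, 5.0, n_subjects)
    max_disp = rng.lognormal(mean=-0.4, sigma=0.75, size=n_subjects)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
            "age": age,
            "sex": sex,
            "site": site,
            "cortical_thickness": thickness,
            "gm_volume": gm_volume,
            "tiv": tiv,
            "brain_age": brain_age,
            "max_displacement": max_disp,
        }
    )


def gen_cohort(
    n_subjects: int = 40,
    n_regions: int = 20,
    n_volumes: int = 204,
    n_sessions: int = 2,
    blocks_per_session: int = 4,
    snr: float = 10.0,
    betas: Sequence[float] = (14.39, -0.03, -0.15, -0.74, 1.02, 0.0),
    outcome_noise_sd: float = 1.71,
    factor_sd: Sequence[float] = (2.0, 1.3, 1.0),
    cog_noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticCohort:
    """A full synthetic cohort wired end-to-end with known truth.

    Each subject gets ``n_sessions`` sessions whose state sequences mix
    redundant and fragile blocks according to a subject-level redundancy
    propensity, so true BFR varies across the cohort.  The episodic latent
    factor is generated from the moderation model (cortical thickness as
    the brain-change measure, true BFR as moderator, coefficients
    ``betas``); semantic and executive factors are independent noise.  The
    default coefficients and residual scale are the episodic-model values
    the analysis is designed to detect.
    """
    rng = np.random.default_rng(seed)
    subjects = gen_subject_table(n_subjects, seed=int(rng.integers(2**31)))
    propensity = rng.uniform(0.1, 0.9, n_subjects)
    state_seqs: dict[tuple[str, str], StateSequence] = {}
    timeseries: dict[tuple[str, str], RegionalTimeseries] = {}
    bfr_true: dict[str, float] = {}
    for i, sid in enumerate(subjects["subject_id"]):
        n_red = 0
        for s in range(n_sessions):
            labels = tuple(
                REDUNDANT if rng.random() < propensity[i] else FRAGILE
                for _ in range(blocks_per_session)
            )
            n_red += sum(l == REDUNDANT for l in labels)
            seq = StateSequence(labels)
            ses = f"ses-{s + 1:02d}"
            state_seqs[(sid, ses)] = seq
            timeseries[(sid, ses)] = gen_timeseries(
                n_regions,
                n_volumes,
                seq,
                snr=snr,
                seed=int(rng.integers(2**31)),
                subject_id=sid,
                session_id=ses,
            )
        bfr_true[sid] = n_red / (n_sessions * blocks_per_session)
    bfr_vec = np.array([bfr_true[s] for s in subjects["subject_id"]])
    episodic = gen_moderated_outcome(
        subjects["cortical_thickness"].to_numpy(),
        bfr_vec,
        subjects["site"].to_numpy(),
        subjects["sex"].to_numpy(),
        betas,
        noise_sd=outcome_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    factor_sd = np.asarray(factor_sd, dtype=float)
    factors = rng.standard_normal((n_subjects, 3)) * factor_sd
    factors[:, 0] = episodic - episodic.mean()
    loadings = default_cognitive_loadings(factor_sd, cog_noise_sd)
    cognitive = gen_cognitive_scores(
        n_subjects,
        loadings,
        factor_sd,
        cog_noise_sd,
        seed=int(rng.integers(2**31)),
        factors=factors,
    )
    cognitive.insert(0, "subject_id", subjects["subject_id"])
    truth = CohortTruth(
        seed=seed,
        betas=tuple(float(b) for b in betas),
        noise_sd=float(outcome_noise_sd),
        loadings=loadings,
        factor_sd=tuple(float(s) for s in factor_sd),
        cog_noise_sd=float(cog_noise_sd),
        snr=float(snr),
        state_sequences=state_seqs,
        bfr_true=bfr_true,
    )
    return SyntheticCohort(
        timeseries=timeseries,
        subjects=subjects,
        cognitive_scores=cognitive,
        truth=truth,
    )
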