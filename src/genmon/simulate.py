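"""Forward simulator for a two-population release into a lake chain.

Emulates a monitored two-population release with known per-individual
ancestry truth:

* Two diverged founder populations A and B (multi-locus FST calibrated to a
  target, default 0.40) produce hatchery fry through small spawner pools
  (about 100 and 17 spawners), which are released into the top of a chain
  of seven lakes.
* Discrete generations.  Each generation, migration happens first —
  downstream-only between adjacent lakes, with a per-individual move
  probability m0 + beta * Q_A that links dispersal tendency to ancestry
  from the migratory founder population — then random mating within each
  deme with the census regulated back to the configured deme size.
* A waterfall at the bottom of the chain leaks fish one-way into a native
  creek deme (Creek I), which itself sends migrants downstream to a second
  native deme (Creek II).  The creeks are initialized from their own
  founder frequencies (pairwise FST calibrated to a target, default 0.21)
  and run in parallel.
* Pedigree ancestry truth (Q per founder source) is transmitted as the
  parental mean, so F1s of A x B crosses have Q_A exactly 0.5.

Loci are unlinked biallelic SNPs; founder frequencies follow the
Balding-Nichols model (Beta around an ancestral frequency with a single
divergence knob F), calibrated by bisection against the realized
Weir-Cockerham theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .divergence import wc_components, _ratios
from .geno_io import AlleleFreqTable, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimState",
    "simulate_founder_freqs",
    "simulate_release_and_spread",
    "sample_population",
    "wright_fisher",
    "offspring_sample",
]

SOURCES = ["A", "B", "CreekI", "CreekII"]


@dataclass
class SimConfig:
    """Parameters of the release-and-spread simulation.

    Defaults describe the emulated monitoring design: 96 SNPs, founder FST 0.40 produced by
    ~100 (A) and 17 (B) spawners with 1000 released fry each, seven lakes
    colonized over 6 generations (~5 years per generation), a one-way
    waterfall into two native creek demes at pre-release FST 0.21.
    """

    n_loci: int = 96
    fst_founders: float = 0.40
    n_spawners_A: int = 100
    n_spawners_B: int = 17
    n_fry_released: int = 1000
    n_lakes: int = 7
    generations: int = 6
    deme_size: int = 250
    creek_sizes: tuple[int, int] = (60, 120)
    downstream_base_rate: float = 0.04   # m0
    ancestry_migration_slope: float = 0.12  # beta: extra move prob per unit Q_A
    waterfall_rate: float = 0.0005       # lake chain -> Creek I, one-way
    creek_downstream_rate: float = 0.02  # Creek I -> Creek II
    creek_fst: float = 0.21
    shared_diagnostic_fraction: float = 0.10
    generation_length_years: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.downstream_base_rate, self.ancestry_migration_slope,
                  self.waterfall_rate, self.creek_downstream_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for t in (self.fst_founders, self.creek_fst):
            if not 0 < t < 1:
                raise ValueError("FST targets must lie in (0, 1)")
        for s in (self.n_loci, self.n_spawners_A, self.n_spawners_B,
                  self.n_fry_released, self.n_lakes, self.generations,
                  self.deme_size, *self.creek_sizes):
            if s < 1:
                raise ValueError("sizes must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "creek_sizes" in raw:
            raw["creek_sizes"] = tuple(raw["creek_sizes"])
        return cls(**raw)


@dataclass
class SimState:
    """Full end state: genotypes, labels and truth for every living fish,
    plus per-generation archived samples of each deme."""

    gm: GenotypeMatrix
    truth: pd.DataFrame          # id, deme, generation, natal_deme, Q_A..Q_CreekII
    founder_freqs: AlleleFreqTable
    config: SimConfig
    history: dict = field(default_factory=dict)  # (deme, generation) -> (dosage, truth rows)


# ---------------------------------------------------------------------------
# Founder frequencies (Balding-Nichols, calibrated)
# ---------------------------------------------------------------------------

def _bn_ppf(u: np.ndarray, p: np.ndarray, F: float) -> np.ndarray:
    """Inverse-CDF Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F).

    Using common uniforms makes the draw a smooth, monotone-ish function of
    F, which keeps the bisection calibration well behaved.
    """
    if F <= 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return sps.beta.ppf(u, a, b)


def _realized_theta(freq_pair: np.ndarray, rng: np.random.Generator,
                    n: int = 500) -> float:
    """Multi-locus Weir-Cockerham theta between two populations, measured on
    large pseudo-samples drawn from the given frequencies."""
    dosages = []
    for p in freq_pair:
        d = rng.binomial(2, p, size=(n, p.size)).astype(np.int16)
        dosages.append(d)
    theta, _, _ = _ratios(wc_components(dosages))
    return theta


def _calibrate_pair(p_anc: np.ndarray, u: np.ndarray, target: float,
                    rng: np.random.Generator, tol: float = 0.01,
                    max_iter: int = 40) -> tuple[np.ndarray, float]:
    """Bisection on the divergence knob F until the realized theta between
    the two derived populations hits the target."""
    lo, hi = 1e-4, 0.95
    # one fixed child seed, reused each iteration, makes theta(F) a
    # deterministic near-monotone function and keeps bisection stable
    sample_seed = int(rng.integers(2 ** 31))
    best = None
    for _ in range(max_iter):
        F = 0.5 * (lo + hi)
        freqs = np.vstack([_bn_ppf(u[i], p_anc, F) for i in range(2)])
        freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
        theta = _realized_theta(freqs, np.random.default_rng(sample_seed))
        if best is None or abs(theta - target) < abs(best[1] - target):
            best = (freqs, theta, F)
        if abs(theta - target) < tol:
            return freqs, F
        if theta < target:
            lo = F
        else:
            hi = F
    if best is None or abs(best[1] - target) > 0.1:
        raise RuntimeError(
            f"founder FST calibration failed: best realized theta "
            f"{best[1]:.3f} vs target {target:.3f}"
        )
    return best[0], best[2]


def simulate_founder_freqs(cfg: SimConfig) -> AlleleFreqTable:
    """Founder allele-frequency table for A, B and the two native creeks.

    Per-locus ancestral frequencies are Uniform(0.05, 0.95); each pair (A/B
    and CreekI/CreekII) is drawn from a Balding-Nichols distribution with
    its divergence knob calibrated by bisection so the realized multi-locus
    Weir-Cockerham theta matches the configured target.  Creek II
    additionally carries, at a fraction of the loci most diagnostic for A
    vs B, a low frequency of the A/B-diagnostic allele (natural pre-release
    polymorphism at otherwise diagnostic markers).
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc_ab = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    u_ab = rng.uniform(1e-6, 1 - 1e-6, size=(2, cfg.n_loci))
    ab, _ = _calibrate_pair(p_anc_ab, u_ab, cfg.fst_founders, rng)

    p_anc_ck = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    u_ck = rng.uniform(1e-6, 1 - 1e-6, size=(2, cfg.n_loci))
    creeks, _ = _calibrate_pair(p_anc_ck, u_ck, cfg.creek_fst, rng)

    # Creek II: share a low frequency of the allele that separates A from B
    # at the most diagnostic loci.
    if cfg.shared_diagnostic_fraction > 0:
        diag = np.argsort(-np.abs(ab[0] - ab[1]))
        n_shared = int(round(cfg.shared_diagnostic_fraction * cfg.n_loci))
        for l in diag[:n_shared]:
            alien = ab[0, l] if ab[0, l] > ab[1, l] else 1 - ab[0, l]
            low = rng.uniform(0.02, 0.15)
            creeks[1, l] = low if ab[0, l] > 0.5 else 1 - low

    freq = np.vstack([ab, creeks])
    copies = np.full(freq.shape, 10_000, dtype=int)   # model frequencies
    loci = [f"snp{i + 1:03d}" for i in range(cfg.n_loci)]
    return AlleleFreqTable(SOURCES, loci, freq, copies)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

class _Deme:
    __slots__ = ("name", "dosage", "q", "natal")

    def __init__(self, name, dosage, q, natal):
        self.name = name
        self.dosage = dosage        # (n, L) int16
        self.q = q                  # (n, 4) pedigree ancestry
        self.natal = natal          # list of natal deme names


def _diploids_from_freqs(freqs: np.ndarray, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int16)


def _mendelian_offspring(dos: np.ndarray, q: np.ndarray, n_off: int,
                         rng: np.random.Generator,
                         name: str) -> tuple[np.ndarray, np.ndarray]:
    """Random mating: each child draws two distinct parents uniformly; each
    parent transmits one allele per locus (binomial thinning of dosage)."""
    n = dos.shape[0]
    if n == 0:
        raise RuntimeError(f"deme {name} extinct")
    if n == 1:
        mothers = fathers = np.zeros(n_off, dtype=int)
    else:
        mothers = rng.integers(0, n, size=n_off)
        shift = rng.integers(1, n, size=n_off)
        fathers = (mothers + shift) % n       # distinct from mother
    pm = dos[mothers] / 2.0
    pf = dos[fathers] / 2.0
    child = (rng.random(pm.shape) < pm).astype(np.int16) \
        + (rng.random(pf.shape) < pf).astype(np.int16)
    child_q = (q[mothers] + q[fathers]) / 2.0
    return child, child_q


def simulate_release_and_spread(
    cfg: SimConfig,
    founder_freqs: AlleleFreqTable | None = None,
    archive_generations: tuple[int, ...] | None = None,
) -> SimState:
    """Run the forward simulation and return the final state with truth.

    Generation 0 holds the released fry (hatchery offspring of the spawner
    pools, placed in lake 1) and the native creek founders.  Each subsequent
    generation applies migration (downstream between adjacent lakes with
    probability ``m0 + beta * Q_A`` per fish, capped at 1; last lake to
    Creek I at the waterfall rate; Creek I to Creek II), then random mating
    regulating each deme back to its configured size.

    ``archive_generations`` selects generations whose per-deme genotypes and
    truth are kept in ``state.history`` (keyed ``(deme, generation)``) for
    temporal sampling; the final generation is always archived.
    """
    if founder_freqs is None:
        founder_freqs = simulate_founder_freqs(cfg)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2 ** 31))
    L = cfg.n_loci
    loci = list(founder_freqs.loci)
    fA, fB, fCI, fCII = founder_freqs.freq

    # hatchery: spawner pools, then fry by random mating within each pool
    spawners_A = _diploids_from_freqs(fA, cfg.n_spawners_A, rng)
    spawners_B = _diploids_from_freqs(fB, cfg.n_spawners_B, rng)
    qa = np.zeros((cfg.n_spawners_A, 4)); qa[:, 0] = 1
    qb = np.zeros((cfg.n_spawners_B, 4)); qb[:, 1] = 1
    fry_A, qA = _mendelian_offspring(spawners_A, qa, cfg.n_fry_released, rng, "hatcheryA")
    fry_B, qB = _mendelian_offspring(spawners_B, qb, cfg.n_fry_released, rng, "hatcheryB")

    lakes = [f"Lake{i + 1}" for i in range(cfg.n_lakes)]
    demes: dict[str, _Deme] = {}
    demes[lakes[0]] = _Deme(
        lakes[0],
        np.vstack([fry_A, fry_B]),
        np.vstack([qA, qB]),
        [lakes[0]] * (2 * cfg.n_fry_released),
    )
    for name in lakes[1:]:
        demes[name] = _Deme(name, np.empty((0, L), np.int16),
                            np.empty((0, 4)), [])
    ci = _diploids_from_freqs(fCI, cfg.creek_sizes[0], rng)
    qci = np.zeros((cfg.creek_sizes[0], 4)); qci[:, 2] = 1
    cii = _diploids_from_freqs(fCII, cfg.creek_sizes[1], rng)
    qcii = np.zeros((cfg.creek_sizes[1], 4)); qcii[:, 3] = 1
    demes["CreekI"] = _Deme("CreekI", ci, qci, ["CreekI"] * cfg.creek_sizes[0])
    demes["CreekII"] = _Deme("CreekII", cii, qcii, ["CreekII"] * cfg.creek_sizes[1])

    target_size = {name: cfg.deme_size for name in lakes}
    target_size["CreekI"], target_size["CreekII"] = cfg.creek_sizes

    archive = set(archive_generations or ()) | {cfg.generations}
    history: dict = {}

    def snap(gen: int) -> None:
        for name, d in demes.items():
            if d.dosage.shape[0]:
                history[(name, gen)] = (d.dosage.copy(), d.q.copy(),
                                        list(d.natal))

    if 0 in archive:
        snap(0)

    order = lakes + ["CreekI", "CreekII"]
    next_lake = {lakes[i]: lakes[i + 1] for i in range(cfg.n_lakes - 1)}

    for gen in range(1, cfg.generations + 1):
        # --- migration (simultaneous, based on start-of-generation state)
        movers: dict[str, list] = {name: [] for name in order}
        for name in order:
            d = demes[name]
            n = d.dosage.shape[0]
            if n == 0:
                continue
            u = rng.random(n)
            if name in next_lake:
                # waterfall leak first (any lake fish can be flushed past the
                # barrier within a generation), then adjacent downstream move
                fall = u < cfg.waterfall_rate
                padj = np.minimum(
                    cfg.downstream_base_rate
                    + cfg.ancestry_migration_slope * d.q[:, 0], 1.0)
                adj = ~fall & (u < cfg.waterfall_rate + (1 - cfg.waterfall_rate) * padj)
                dests = [("CreekI", fall), (next_lake[name], adj)]
            elif name == lakes[-1]:
                fall = u < cfg.waterfall_rate
                dests = [("CreekI", fall)]
            elif name == "CreekI":
                go = u < cfg.creek_downstream_rate
                dests = [("CreekII", go)]
            else:
                dests = []
            gone = np.zeros(n, dtype=bool)
            for dest, mask in dests:
                if mask.any():
                    movers[dest].append(
                        (d.dosage[mask], d.q[mask],
                         [d.natal[i] for i in np.flatnonzero(mask)])
                    )
                    gone |= mask
            stay = ~gone
            d.dosage = d.dosage[stay]
            d.q = d.q[stay]
            d.natal = [d.natal[i] for i in np.flatnonzero(stay)]
        for name, chunks in movers.items():
            if not chunks:
                continue
            d = demes[name]
            d.dosage = np.vstack([d.dosage] + [c[0] for c in chunks])
            d.q = np.vstack([d.q] + [c[1] for c in chunks])
            for c in chunks:
                d.natal.extend(c[2])

        # --- reproduction: regulate each occupied deme to its target size
        for name in order:
            d = demes[name]
            n = d.dosage.shape[0]
            if n == 0:
                if name in ("CreekI", "CreekII"):
                    raise RuntimeError(
                        f"deme {name} extinct at generation {gen}")
                continue
            child, child_q = _mendelian_offspring(
                d.dosage, d.q, target_size[name], rng, name)
            d.dosage, d.q = child, child_q
            d.natal = [name] * target_size[name]

        if gen in archive:
            snap(gen)

    # --- final assembled matrix
    ids, labels, dosages, qs, natal, gens = [], [], [], [], [], []
    for name in order:
        d = demes[name]
        for i in range(d.dosage.shape[0]):
            ids.append(f"{name}_g{cfg.generations}_{i}")
            labels.append(name)
            natal.append(d.natal[i])
            gens.append(cfg.generations)
        if d.dosage.shape[0]:
            dosages.append(d.dosage)
            qs.append(d.q)
    dosage = np.vstack(dosages)
    q = np.vstack(qs)
    truth = pd.DataFrame(
        dict(id=ids, deme=labels, generation=gens, natal_deme=natal,
             Q_A=q[:, 0], Q_B=q[:, 1], Q_CreekI=q[:, 2], Q_CreekII=q[:, 3])
    )
    gm = GenotypeMatrix(ids, loci, dosage, labels, truth=truth)
    return SimState(gm=gm, truth=truth, founder_freqs=founder_freqs,
                    config=cfg, history=history)


def wright_fisher(
    n_diploid: int,
    n_loci: int,
    generations: int,
    seed: int,
    init_freq_range: tuple[float, float] = (0.2, 0.8),
) -> tuple[np.ndarray, np.random.Generator]:
    """Plain neutral Wright-Fisher population of unlinked biallelic loci.

    Starts from Uniform(init range) frequencies, runs ``generations`` rounds
    of random mating at constant size.  Returns the final breeder dosage
    matrix and the generator (for drawing offspring samples), so callers can
    build drift-calibration and estimator-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(*init_freq_range, size=n_loci)
    dos = rng.binomial(2, p0, size=(n_diploid, n_loci)).astype(np.int16)
    for _ in range(generations):
        dos = offspring_sample(dos, n_diploid, rng)
    return dos, rng


def offspring_sample(breeders: np.ndarray, n_offspring: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Offspring cohort of random-mating breeders (two distinct parents per
    child, Mendelian transmission).  Drawing a cohort that is then removed
    is exactly sampling plan II of the temporal method."""
    n = breeders.shape[0]
    m = rng.integers(0, n, n_offspring)
    f = (m + rng.integers(1, max(n, 2), n_offspring)) % n
    return ((rng.random((n_offspring, breeders.shape[1])) < breeders[m] / 2)
            .astype(np.int16)
            + (rng.random((n_offspring, breeders.shape[1])) < breeders[f] / 2)
            .astype(np.int16))


def sample_population(
    state: SimState, deme: str, generation: int, n: int, seed: int,
    year: int | None = None,
) -> GenotypeMatrix:
    """Sample ``n`` individuals without replacement from an archived deme
    generation; carries the truth linkage for recovery tests."""
    key = (deme, generation)
    if key not in state.history:
        raise KeyError(f"deme {deme!r} not archived at generation {generation}")
    dosage, q, natal = state.history[key]
    census = dosage.shape[0]
    if n > census:
        raise ValueError(f"n={n} exceeds census {census} of {deme} at g{generation}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(census, size=n, replace=False)
    ids = [f"{deme}_g{generation}_{i}" for i in pick]
    if year is None:
        year = generation * state.config.generation_length_years
    truth = pd.DataFrame(
        dict(id=ids, deme=deme, generation=generation,
             natal_deme=[natal[i] for i in pick],
             Q_A=q[pick, 0], Q_B=q[pick, 1],
             Q_CreekI=q[pick, 2], Q_CreekII=q[pick, 3])
    )
    return GenotypeMatrix(ids, list(state.gm.loci), dosage[pick],
                          [deme] * n, year=[year] * n, truth=truth)
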