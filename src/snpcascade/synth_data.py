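"""Structured genotype simulation under the Balding-Nichols F-model.

Populations diverge from a shared ancestral allele frequency ``p`` (drawn
uniformly within bounds) by drift parameterized with the fixation index
``F``: each population's frequency is Beta-distributed with mean ``p`` and
variance ``F p (1-p)``.  Diploid genotypes are then Binomial(2, freq) at
each locus — Hardy-Weinberg within populations, no linkage (the target
panels space SNPs hundreds of kilobases apart, so independence is a
reasonable fixture assumption).  Admixed samples draw genotypes from a
per-sample mixture of population frequencies; missingness is applied
completely at random.  A seed fixes the entire output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class SimSpec:
    """Parameters of a population-structure simulation.

    ``admixture`` optionally maps extra sample names to mixing-proportion
    vectors over the populations (rows sum to 1).
    """

    n_populations: int = 4
    samples_per_population: int = 50
    n_loci: int = 300
    fst: float = 0.15
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    admixture: dict[str, np.ndarray] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.freq_bounds
        if not 0 <= lo < hi <= 1:
            raise ValueError("freq_bounds must satisfy 0 <= lo < hi <= 1")
        if self.n_populations < 1 or self.samples_per_population < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if self.admixture:
            for name, q in self.admixture.items():
                q = np.asarray(q, dtype=float)
                if q.shape != (self.n_populations,) or not np.isclose(q.sum(), 1.0):
                    raise ValueError(f"admixture weights for {name!r} invalid")


def _population_frequencies(spec: SimSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = spec.freq_bounds
    anc = rng.uniform(lo, hi, size=spec.n_loci)
    if spec.fst == 0:
        pf = np.tile(anc, (spec.n_populations, 1))
    else:
        a = anc * (1 - spec.fst) / spec.fst
        b = (1 - anc) * (1 - spec.fst) / spec.fst
        pf = rng.beta(a, b, size=(spec.n_populations, spec.n_loci))
    return anc, pf


def simulate_populations(
    spec: SimSpec,
) -> tuple[GenotypeMatrix, list[str], np.ndarray]:
    """Simulate structured genotypes; returns (matrix, labels, true freqs).

    Labels are ``pop1 .. popK``; admixed extras (if any) are labeled
    ``admixed``.  ``true_freqs`` is the ``(K, n_loci)`` array of realized
    population allele frequencies.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    _, pf = _population_frequencies(spec, rng)
    K, L, n = spec.n_populations, spec.n_loci, spec.samples_per_population

    sample_ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for k in range(K):
        G = rng.binomial(2, pf[k], size=(n, L)).astype(np.int8)
        blocks.append(G)
        sample_ids += [f"pop{k + 1}_s{i + 1:03d}" for i in range(n)]
        labels += [f"pop{k + 1}"] * n
    if spec.admixture:
        for name, q in spec.admixture.items():
            q = np.asarray(q, dtype=float)
            mixed = q @ pf
            blocks.append(rng.binomial(2, mixed, size=(1, L)).astype(np.int8))
            sample_ids.append(name)
            labels.append("admixed")
    values = np.vstack(blocks)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.int8(MISSING), values)
    gm = GenotypeMatrix(sample_ids, [f"L{j + 1:04d}" for j in range(L)], values)
    return gm, labels, pf


def simulate_hybrid_cline(
    spec: SimSpec,
    q_grid,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate admixed samples along an ancestry cline between two parents.

    Each entry of ``q_grid`` (ancestry proportion in [0,1] of the second
    parental population) yields one sample whose per-locus allele
    frequency is ``(1-q) p_A + q p_B``.  q=0 / q=1 reproduce the parental
    simulators in expectation; PC1 of the output is monotone in q.
    """
    spec.validate()
    q = np.asarray(q_grid, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q_grid values must be in [0, 1]")
    if spec.n_populations < 2:
        raise ValueError("need two parental populations")
    rng = np.random.default_rng(spec.seed)
    _, pf = _population_frequencies(spec, rng)
    pA, pB = pf[0], pf[1]
    freqs = (1 - q)[:, None] * pA[None, :] + q[:, None] * pB[None, :]
    values = rng.binomial(2, freqs).astype(np.int8)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.int8(MISSING), values)
    gm = GenotypeMatrix(
        [f"hyb_q{qi:.3f}_{i + 1:03d}" for i, qi in enumerate(q)],
        [f"L{j + 1:04d}" for j in range(spec.n_loci)],
        values,
    )
    return gm, q


def planted_panel(
    n_background: int = 490,
    n_diagnostic: int = 10,
    f_background: float = 0.01,
    f_diagnostic: float = 0.5,
    min_diff: float = 0.5,
    n_populations: int = 2,
    samples_per_population: int = 40,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[str], list[str]]:
    """Simulate a locus pool with a known planted diagnostic subset.

    Background loci drift weakly (``f_background``).  The planted loci
    drift strongly (``f_diagnostic``) *and* are conditioned (rejection
    sampling) on a realized population frequency spread of at least
    ``min_diff`` — a planted locus must actually be diagnostic for a
    recovery experiment to be well-posed, since an unconditioned strong
    drift draw can still leave both populations at the same frequency.
    Returns the matrix, the labels, and the planted locus ids.
    """
    rng = np.random.default_rng(seed)
    bg_spec = SimSpec(
        n_populations=n_populations,
        samples_per_population=samples_per_population,
        n_loci=n_background,
        fst=f_background,
        seed=int(rng.integers(2**31 - 1)),
    )
    gm_bg, labels, _ = simulate_populations(bg_spec)

    # diagnostic population frequencies: strong drift, conditioned diagnostic
    dx_spec = SimSpec(
        n_populations=n_populations,
        samples_per_population=samples_per_population,
        n_loci=1,
        fst=f_diagnostic,
        seed=seed,
    )
    cols = []
    accepted = 0
    while accepted < n_diagnostic:
        _, pf = _population_frequencies(
            SimSpec(**{**dx_spec.__dict__, "n_loci": n_diagnostic}), rng
        )
        spread = pf.max(axis=0) - pf.min(axis=0)
        for j in np.where(spread >= min_diff)[0]:
            if accepted == n_diagnostic:
                break
            col = np.concatenate(
                [
                    rng.binomial(2, pf[k, j], size=samples_per_population)
                    for k in range(n_populations)
                ]
            ).astype(np.int8)
            cols.append(col)
            accepted += 1
    planted = [f"DIAG{j + 1:03d}" for j in range(n_diagnostic)]
    order = rng.permutation(n_background + n_diagnostic)
    all_ids = np.array(gm_bg.locus_ids + planted)[order]
    all_vals = np.hstack([gm_bg.values, np.stack(cols, axis=1)])[:, order]
    gm = GenotypeMatrix(gm_bg.sample_ids, list(all_ids), all_vals)
    return gm, labels, planted
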