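"""Reference-set population assignment by frequency likelihood or distance.

A classical comparator for the cascade classifier: per-population
alt-allele frequencies are estimated from a labeled reference panel (with
a pseudocount so no frequency is exactly 0 or 1), and an unknown sample is
ranked against every population either by the log-likelihood of its
genotypes under Hardy-Weinberg proportions or by the Euclidean distance
between its allele-dosage profile and the population frequency vector.
The winner is the best-scoring population; results are sensitive to the
composition of the reference set — adding a genetically closer reference
population can change the winning label for admixed samples.

GenePop-format read/write is provided for interoperability with classical
assignment software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class PopulationFrequencies:
    """Per-locus alt-allele frequencies for one reference population."""

    label: str
    locus_ids: list[str]
    freqs: np.ndarray  # in (0,1) after pseudocount
    n_samples: int


@dataclass
class Assignment:
    """Ranked populations for one sample (best first)."""

    sample_id: str
    ranking: list[str]
    scores: dict[str, float]
    method: str
    ambiguous: bool

    @property
    def winner(self) -> str:
        return self.ranking[0]


def estimate_frequencies(
    gm: GenotypeMatrix,
    labels: Sequence[str],
    pseudocount: float = 0.5,
) -> list[PopulationFrequencies]:
    """Estimate per-population alt-allele frequencies with a pseudocount.

    ``freq = (alt count + pseudocount) / (2 * n_nonmissing + 2 * pseudocount)``
    per locus; a positive pseudocount keeps fixed loci away from 0/1 so
    log-likelihoods stay finite.
    """
    labels = [str(l) for l in labels]
    if len(labels) != gm.n_samples:
        raise ValueError("labels length must equal number of samples")
    out = []
    for pop in sorted(set(labels)):
        rows = [i for i, l in enumerate(labels) if l == pop]
        if not rows:
            raise ValueError(f"empty population {pop!r}")
        V = gm.values[rows]
        obs = V != MISSING
        alt = np.where(obs, V, 0).sum(axis=0).astype(float)
        n_obs = obs.sum(axis=0).astype(float)
        freqs = (alt + pseudocount) / (2.0 * n_obs + 2.0 * pseudocount)
        out.append(
            PopulationFrequencies(pop, list(gm.locus_ids), freqs, len(rows))
        )
    return out


def _hwe_log_probs(freqs: np.ndarray) -> np.ndarray:
    """(3, n_loci) log genotype probabilities under HWE."""
    p = freqs
    return np.log(
        np.vstack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    )


def assign_sample(
    freqs: Sequence[PopulationFrequencies],
    genotypes: np.ndarray,
    sample_id: str = "sample",
    method: str = "loglik",
) -> Assignment:
    """Rank reference populations for one 0/1/2(/missing) genotype vector.

    ``loglik``: sum over non-missing loci of the log HWE genotype
    probability under the population's frequencies.  ``distance``:
    (negated) Euclidean distance between dosage/2 and the frequency
    vector.  Missing loci are skipped; ties break lexicographically and
    flag the result ambiguous.
    """
    if method not in ("loglik", "distance"):
        raise ValueError("method must be 'loglik' or 'distance'")
    g = np.asarray(genotypes)
    obs = g != MISSING
    if not obs.any():
        raise ValueError("no shared non-missing locus")
    scores: dict[str, float] = {}
    for pf in freqs:
        if len(pf.freqs) != len(g):
            raise ValueError("genotype vector does not match reference loci")
        if method == "loglik":
            lp = _hwe_log_probs(pf.freqs)
            scores[pf.label] = float(lp[g[obs], np.where(obs)[0]].sum())
        else:
            d = g[obs] / 2.0 - pf.freqs[obs]
            scores[pf.label] = -float(np.sqrt((d**2).sum()))
    ranking = sorted(scores, key=lambda k: (-scores[k], k))
    ambiguous = len(ranking) > 1 and np.isclose(
        scores[ranking[0]], scores[ranking[1]]
    )
    return Assignment(sample_id, ranking, scores, method, bool(ambiguous))


def assign_matrix(
    freqs: Sequence[PopulationFrequencies],
    gm: GenotypeMatrix,
    method: str = "loglik",
) -> list[Assignment]:
    """Assign every sample of a matrix (loci aligned to the reference's)."""
    ref_loci = freqs[0].locus_ids
    sub = gm.subset(loci=[l for l in ref_loci if l in set(gm.locus_ids)])
    aligned = np.full((gm.n_samples, len(ref_loci)), MISSING, dtype=np.int8)
    pos = {l: k for k, l in enumerate(ref_loci)}
    for j, l in enumerate(sub.locus_ids):
        aligned[:, pos[l]] = sub.values[:, j]
    return [
        assign_sample(freqs, aligned[i], sid, method)
        for i, sid in enumerate(gm.sample_ids)
    ]


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

_GT_TO_GENEPOP = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}


def write_genepop(gm: GenotypeMatrix, labels: Sequence[str], path, title="snpcascade export") -> None:
    """Write genotypes in two-digit-allele GenePop format, one Pop per label."""
    labels = [str(l) for l in labels]
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for l in gm.locus_ids:
            fh.write(l + "\n")
        for pop in sorted(set(labels)):
            fh.write("Pop\n")
            for i, sid in enumerate(gm.sample_ids):
                if labels[i] != pop:
                    continue
                alleles = " ".join(_GT_TO_GENEPOP[int(v)] for v in gm.values[i])
                fh.write(f"{sid} ,  {alleles}\n")


def read_genepop(path) -> tuple[GenotypeMatrix, list[str]]:
    """Read a two-digit-allele GenePop file into a 0/1/2 matrix + pop labels.

    Allele 01 is taken as reference and 02 as alternate; ``0000`` is
    missing.  Populations are named pop1, pop2, ... in file order.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty GenePop file")
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for tok in lines[i].split(","):
            tok = tok.strip()
            if tok:
                locus_ids.append(tok)
        i += 1
    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[list[int]] = []
    pop = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop += 1
            continue
        if "," not in line:
            raise ValueError(f"{path}: malformed sample line {line!r}")
        sid, rest = line.split(",", 1)
        calls = rest.split()
        if len(calls) != len(locus_ids):
            raise ValueError(
                f"{path}: sample {sid.strip()!r} has {len(calls)} calls "
                f"for {len(locus_ids)} loci"
            )
        row = []
        for c in calls:
            if c == "0000" or c == "000000":
                row.append(MISSING)
            else:
                a1, a2 = int(c[: len(c) // 2]), int(c[len(c) // 2 :])
                row.append((a1 == 2) + (a2 == 2))
        sample_ids.append(sid.strip())
        labels.append(f"pop{pop}")
        rows.append(row)
    return GenotypeMatrix(sample_ids, locus_ids, np.array(rows, dtype=np.int8)), labels
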