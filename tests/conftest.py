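"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from ltr_cisnet.ltr_detection import DetectionParams, _tsd_at
from ltr_cisnet.synthetic_data import generate_genome, plant_element

GAP_OPEN, GAP_EXTEND = 2, 1


def align_oracle(a: str, b: str) -> tuple[int, int, int]:
    """Pure-python lexicographic (score, matches, -columns) global aligner.

    Independent of the numpy implementation: three-state memoised recursion
    over (i, j, state) with affine gaps (open 2 + extend 1, i.e. a first gap
    column costs 3).
    """
    NEG = (-10**9, -10**9, -10**9)

    @functools.lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == 0 and j == 0:
            return (0, 0, 0) if state == -1 else NEG
        best = NEG
        if state == 0 and i > 0 and j > 0:
            s = 1 if a[i - 1] == b[j - 1] else -1
            m = 1 if a[i - 1] == b[j - 1] else 0
            for st in (-1, 0, 1, 2):
                v = rec(i - 1, j - 1, st)
                cand = (v[0] + s, v[1] + m, v[2] - 1)
                best = max(best, cand)
        elif state == 1 and i > 0:
            for st in (-1, 0, 1, 2):
                v = rec(i - 1, j, st)
                pen = GAP_EXTEND if st == 1 else GAP_OPEN + GAP_EXTEND
                best = max(best, (v[0] - pen, v[1], v[2] - 1))
        elif state == 2 and j > 0:
            for st in (-1, 0, 1, 2):
                v = rec(i, j - 1, st)
                pen = GAP_EXTEND if st == 2 else GAP_OPEN + GAP_EXTEND
                best = max(best, (v[0] - pen, v[1], v[2] - 1))
        return best

    score, matches, negcols = max(rec(len(a), len(b), st) for st in (0, 1, 2))
    rec.cache_clear()
    return score, matches, -negcols


def brute_force_detect(genome, params: DetectionParams):
    """All-substring-pair LTR search under the detection criteria.

    Enumerates every (element start, element end, LTR length) triple whose
    two equal-length repeat copies reach the identity threshold (Hamming;
    the fixtures are substitution-only, for which the affine-gap optimum is
    the ungapped diagonal), whose separation is in range and which carries a
    flanking TSD; then greedily resolves overlaps with the same structural
    preference as the detector (ungapped score + TSD length, shorter LTR,
    leftmost).  Tractable only at reduced length/separation parameters.
    """
    out = []
    for scaf in sorted(genome):
        seq = genome[scaf].upper()
        arr = np.frombuffer(seq.encode(), np.uint8)
        n = arr.size
        cands = []
        d_lo = params.min_ltr_len + params.min_sep
        d_hi = params.max_ltr_len + params.max_sep
        for d in range(d_lo, min(d_hi, n - params.min_ltr_len) + 1):
            m = (arr[:n - d] == arr[d:]).astype(np.int64)
            csum = np.concatenate([[0], np.cumsum(m)])
            for L in range(params.min_ltr_len, params.max_ltr_len + 1):
                sep = d - L
                if not (params.min_sep <= sep <= params.max_sep):
                    continue
                if L > n - d:
                    break
                ham = (csum[L:] - csum[:-L]) / L
                for a in np.nonzero(ham >= params.min_identity)[0]:
                    a = int(a)
                    end = a + d + L
                    if end > n:
                        continue
                    tsd = _tsd_at(seq, a, end, params.tsd_len_range)
                    if params.require_tsd and tsd is None:
                        continue
                    matches = int(csum[a + L] - csum[a])
                    score = 2 * matches - L + (len(tsd) if tsd else 0)
                    cands.append(((score, -L, -a), a, end, L, tsd))
        cands.sort(reverse=True)
        kept = []
        for _key, a, end, L, tsd in cands:
            if any(a < k[2] and k[1] < end for k in kept):
                continue
            kept.append((scaf, a, end, L, tsd))
        out.extend(sorted(kept, key=lambda x: x[1]))
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_peptide(rng: np.random.Generator, n: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def planted_genome():
    """One 50-kb scaffold with a single planted full-length element."""
    g = generate_genome(1, 50_000, 0.35, seed=7)
    g, truth = plant_element(g, "scf_1", 20_000, ltr_len=300, internal_len=5000,
                             identity=0.85, tsd_len=4, domains=("pol",), seed=3)
    return g, truth
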