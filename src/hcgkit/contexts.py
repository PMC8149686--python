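"""Cytosine-context inference from genome sequence.

Plant cytosine methylation is reported in three sequence contexts: CG, CHG
and CHH (H = A, T or C), assigned per cytosine on both strands.  On the plus
strand a cytosine at 0-based index ``i`` is CG when ``seq[i+1] == 'G'``, CHG
when ``seq[i+2] == 'G'`` and CHH otherwise; the minus strand mirrors this on
the reverse complement.  A cytosine whose downstream bases fall off the
chromosome end (or contain an ambiguous base) has an unresolvable context and
is skipped rather than guessed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: canonical context labels, in fixed code order (0, 1, 2)
CONTEXTS = ("CG", "CHG", "CHH")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

_COMP = np.full(256, _N, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP[_x] = _y


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return _COMP[_encode(seq)][::-1].tobytes().decode("ascii")


def _tri_strings(mat: np.ndarray) -> np.ndarray:
    # (n, 3) uint8 -> array of 3-mers
    mat = np.ascontiguousarray(mat, dtype=np.uint8)
    return mat.view("S3")[:, 0].astype("U3")


def chromosome_cytosines(chrom: str, seq: str) -> pd.DataFrame:
    """Context table for every resolvable cytosine on both strands.

    Returns columns ``chrom, pos (1-based), strand, context, trinucleotide``,
    sorted by position (plus before minus at the same position).
    """
    arr = _encode(seq)
    n = arr.size
    pad = np.concatenate([np.full(2, _N, np.uint8), arr, np.full(2, _N, np.uint8)])
    # pad index of genomic i is i + 2

    frames = []

    # plus strand: C at i, context from i+1 / i+2
    ci = np.flatnonzero(arr == _C)
    ci = ci[ci < n - 1]
    if ci.size:
        nxt = arr[ci + 1]
        cg = ci[nxt == _G]
        # CHG/CHH need a resolvable H one downstream and any base two downstream
        rest = ci[np.isin(nxt, (_A, _C, _T))]
        rest = rest[rest < n - 2]
        third = arr[rest + 2]
        ok = np.isin(third, (_A, _C, _G, _T))
        rest, third = rest[ok], third[ok]
        codes = np.concatenate(
            [np.zeros(cg.size, np.uint8), np.where(third == _G, 1, 2).astype(np.uint8)]
        )
        pos = np.concatenate([cg, rest])
        tri = _tri_strings(np.stack([pad[pos + 2], pad[pos + 3], pad[pos + 4]], axis=1))
        frames.append(
            pd.DataFrame(
                {
                    "pos": pos + 1,
                    "strand": "+",
                    "context": pd.Categorical.from_codes(codes, CONTEXTS),
                    "trinucleotide": tri,
                }
            )
        )

    # minus strand: G at i on plus == C on minus; context from i-1 / i-2
    gi = np.flatnonzero(arr == _G)
    gi = gi[gi >= 1]
    if gi.size:
        prv = arr[gi - 1]
        cg = gi[prv == _C]
        rest = gi[np.isin(prv, (_A, _G, _T))]  # H on minus strand = A/G/T on plus
        rest = rest[rest >= 2]
        third = arr[rest - 2]
        ok = np.isin(third, (_A, _C, _G, _T))
        rest, third = rest[ok], third[ok]
        codes = np.concatenate(
            [np.zeros(cg.size, np.uint8), np.where(third == _C, 1, 2).astype(np.uint8)]
        )
        pos = np.concatenate([cg, rest])
        tri = _tri_strings(
            np.stack(
                [_COMP[pad[pos + 2]], _COMP[pad[pos + 1]], _COMP[pad[pos]]], axis=1
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "pos": pos + 1,
                    "strand": "-",
                    "context": pd.Categorical.from_codes(codes, CONTEXTS),
                    "trinucleotide": tri,
                }
            )
        )

    if not frames:
        df = pd.DataFrame(
            {
                "pos": np.array([], dtype=np.int64),
                "strand": pd.array([], dtype="str"),
                "context": pd.Categorical([], categories=CONTEXTS),
                "trinucleotide": pd.array([], dtype="str"),
            }
        )
    else:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["pos", "strand"], kind="stable", ignore_index=True)
    df.insert(0, "chrom", chrom)
    return df


def cytosine_contexts(genome: Mapping[str, str]) -> pd.DataFrame:
    """Genome-wide cytosine context map (all chromosomes, both strands)."""
    parts = [chromosome_cytosines(c, genome[c]) for c in genome]
    return pd.concat(parts, ignore_index=True) if parts else chromosome_cytosines("", "")
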