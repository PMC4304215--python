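"""File I/O: FASTA and dot-bracket input, TSV/JSON distribution output,
and deterministic fixture generation."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .energy import EnergyModel
from .errors import InputError
from .landscape import Distribution2D
from .score_engine import ScoreDistribution
from .structures import (
    ENUMERATION_CAP,
    RnaSequence,
    SecondaryStructure,
    enumerate_structures,
    parse_dot_bracket,
)

SPARSITY_EPS = 1e-12  # 2D cells below this probability are written as 0


def read_fasta(path) -> RnaSequence:
    """First record of a FASTA file as an RnaSequence (T normalized to U);
    additional records are ignored with a warning."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} holds {len(records)} records; using the first "
            f"({records[0].id})"
        )
    return RnaSequence.from_string(str(records[0].seq))


def read_structure(path, n: int | None = None) -> SecondaryStructure:
    """Dot-bracket structure from a plain-text file (first non-empty,
    non-comment line)."""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith(("#", ">")):
            return parse_dot_bracket(line, n)
    raise InputError(f"no dot-bracket line found in {path}")


def _header(seq: RnaSequence, model: EnergyModel, backend: str, s_max,
            Z: float, extra: dict | None = None) -> dict:
    meta = {
        "sequence_sha256": hashlib.sha256(seq.residues.encode()).hexdigest(),
        "n": seq.n,
        "model": model.to_config(),
        "backend": backend,
        "s_max": s_max,
        "Z": Z,
    }
    if extra:
        meta.update(extra)
    return meta


def write_distribution(dist, path, format: str = "tsv", *,
                       seq: RnaSequence | None = None,
                       model: EnergyModel | None = None,
                       backend: str = "", extra: dict | None = None) -> None:
    """Write a 1D or 2D distribution as TSV (with '#'-prefixed metadata
    header) or JSON.  Probabilities carry 12 significant digits."""
    path = Path(path)
    is2d = isinstance(dist, Distribution2D)
    s_max = [dist.s1_max, dist.s2_max] if is2d else dist.s_max
    meta = _header(seq, model, backend, s_max, dist.Z, extra) \
        if seq is not None and model is not None else {"Z": dist.Z, "s_max": s_max}
    if format == "json":
        payload = dict(meta)
        if is2d:
            payload["cells"] = [
                {"d1": int(a), "d2": int(b),
                 "weight": float(dist.z[a, b]),
                 "probability": float(dist.p[a, b])}
                for a, b in zip(*np.nonzero(dist.p > SPARSITY_EPS))
            ]
        else:
            payload["scores"] = list(range(dist.s_max + 1))
            payload["weights"] = [float(v) for v in dist.z]
            payload["probabilities"] = [float(v) for v in dist.p]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if format != "tsv":
        raise InputError(f"unknown output format {format!r}")
    lines = [f"# {k}: {json.dumps(v) if isinstance(v, dict) else v}"
             for k, v in meta.items()]
    if is2d:
        lines.append("d1\td2\tweight\tprobability")
        for a, b in zip(*np.nonzero(dist.p > SPARSITY_EPS)):
            lines.append(
                f"{a}\t{b}\t{dist.z[a, b]:.12g}\t{dist.p[a, b]:.12g}"
            )
    else:
        lines.append("score\tweight\tprobability")
        for s in range(dist.s_max + 1):
            lines.append(f"{s}\t{dist.z[s]:.12g}\t{dist.p[s]:.12g}")
    path.write_text("\n".join(lines) + "\n")


def read_distribution_tsv(path) -> ScoreDistribution:
    """Re-read a 1D TSV written by :func:`write_distribution` (round-trip
    to printed precision; used for checks and plotting)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or line.startswith("score\t") or not line.strip():
            continue
        _, w, _ = line.split("\t")
        rows.append(float(w))
    return ScoreDistribution(np.array(rows))


def generate_fixture(n: int, seed: int, model: EnergyModel,
                     cap: int = ENUMERATION_CAP
                     ) -> tuple[RnaSequence, SecondaryStructure]:
    """Deterministic pseudo-random (sequence, reference structure) pair.

    The sequence is uniform over A/C/G/U.  For n within the enumeration
    cap the reference is drawn uniformly from the ensemble; beyond it,
    admissible pairs are greedily accepted in random order (always
    yielding a valid structure).  Identical (n, seed) give identical
    output.
    """
    rng = np.random.default_rng(seed)
    seq = RnaSequence("".join(rng.choice(list("ACGU"), size=n)))
    if n <= cap:
        structures = list(enumerate_structures(seq, model, cap=cap))
        ref = structures[int(rng.integers(len(structures)))]
        return seq, ref
    candidates = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + model.theta + 1, n + 1)
        if model.pair_allowed(seq.base(i), seq.base(j))
    ]
    rng.shuffle(candidates)
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for i, j in candidates:
        if i in used or j in used:
            continue
        if any(k < i <= l < j or i < k <= j < l for k, l in chosen):
            continue
        chosen.append((i, j))
        used.add(i)
        used.add(j)
    return seq, SecondaryStructure(n=n, pairs=frozenset(chosen))
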