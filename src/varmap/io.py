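"""Readers and writers for the pipeline's interchange formats.

Count tables travel as TSV, score maps as MaveDB-style CSV (``hgvs_pro``,
``score``, ``sd``, ``se`` plus extended columns), reference sequences as
FASTA, and simulated read pairs as a FASTQ pair (``/1`` and ``/2`` files).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibration import EvidenceThresholds, LlrCalibration
from .counting import CountTable, ReadPair
from .errors import MalformedInputError
from .variants import VariantKey


def write_fasta(sequence: str, path: str | Path, name: str = "reference") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedInputError(f"no sequences in {path}")
    return str(records[0].seq)


def write_fastq_pairs(
    pairs: Iterable[ReadPair], prefix: str | Path
) -> tuple[Path, Path]:
    """Write read pairs to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    prefix = Path(prefix)
    path_1 = prefix.with_name(prefix.name + "_1.fastq")
    path_2 = prefix.with_name(prefix.name + "_2.fastq")
    with open(path_1, "w") as f1, open(path_2, "w") as f2:
        for i, pair in enumerate(pairs):
            name = f"pair{i}:tile{pair.tile_id}:offset{pair.offset}"
            f1.write(f"@{name}/1\n{pair.calls_fwd}\n+\n{pair.quals_fwd}\n")
            f2.write(f"@{name}/2\n{pair.calls_rev}\n+\n{pair.quals_rev}\n")
    return path_1, path_2


def read_fastq_pairs(path_1: str | Path, path_2: str | Path) -> list[ReadPair]:
    """Rebuild read pairs from a FASTQ pair written by :func:`write_fastq_pairs`."""
    pairs = []
    recs_1 = list(SeqIO.parse(str(path_1), "fastq"))
    recs_2 = list(SeqIO.parse(str(path_2), "fastq"))
    if len(recs_1) != len(recs_2):
        raise MalformedInputError("FASTQ mates have different read counts")
    for r1, r2 in zip(recs_1, recs_2):
        name_parts = r1.id.removesuffix("/1").split(":")
        tile_id = int(name_parts[1].removeprefix("tile"))
        offset = int(name_parts[2].removeprefix("offset"))
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        pairs.append(
            ReadPair(tile_id, offset, str(r1.seq), str(r2.seq), q1, q2)
        )
    return pairs


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> CountTable:
    frame = pd.read_csv(path, sep="\t")
    counts: dict[VariantKey, int] = {}
    depth: dict[int, int] = {}
    tile_bounds: dict[int, tuple[int, int]] = {}
    condition = str(frame["condition"].iloc[0]) if len(frame) else "nonselective"
    replicate = int(frame["replicate"].iloc[0]) if len(frame) else 1
    for _, row in frame.iterrows():
        key = VariantKey(int(row["pos"]), str(row["ref"]), str(row["alt"]))
        counts[key] = int(row["count"])
        # reconstruct a per-codon pseudo-tile so frequencies round-trip
        nt = (key.pos - 1) * 3
        tile_id = len(tile_bounds)
        existing = [t for t, (s, e) in tile_bounds.items() if s <= nt < e]
        if existing:
            tile_id = existing[0]
        else:
            tile_bounds[tile_id] = (nt, nt + 3)
            depth[tile_id] = int(row["depth"])
    return CountTable(condition, replicate, counts, depth, tile_bounds)


def write_mavedb_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score map as MaveDB-style CSV.

    ``scores`` is indexed by (pos, ref, alt) and carries at least ``fs`` and
    ``sigma``; extended columns present in the frame (``region``,
    ``passed_filters``, ``delta`` ...) are appended after the standard
    ``hgvs_pro, score, sd, se`` block.
    """
    out = pd.DataFrame(
        {
            "hgvs_pro": [
                VariantKey(pos, ref, alt).hgvs_pro()
                for pos, ref, alt in scores.index
            ],
            "score": scores["fs"].to_numpy(),
            "sd": (scores["sigma"] * np.sqrt(scores.get("n_rep", 1))).to_numpy(),
            "se": scores["sigma"].to_numpy(),
        }
    )
    for col in scores.columns:
        if col not in ("fs", "sigma"):
            out[col] = scores[col].to_numpy()
    out.to_csv(path, index=False)


def write_tile_map(
    tile_bounds: dict[int, tuple[int, int]], path: str | Path
) -> None:
    """Tile map TSV: tile_id, start, end (0-based, half-open nucleotides)."""
    pd.DataFrame(
        [
            {"tile_id": tid, "start": s, "end": e}
            for tid, (s, e) in sorted(tile_bounds.items())
        ]
    ).to_csv(path, sep="\t", index=False)


def read_tile_map(path: str | Path) -> dict[int, tuple[int, int]]:
    frame = pd.read_csv(path, sep="\t")
    return {
        int(r["tile_id"]): (int(r["start"]), int(r["end"]))
        for _, r in frame.iterrows()
    }


def write_clone_pool(pool, path: str | Path) -> None:
    """Clone pool TSV: one row per clone with its variants and abundance."""
    rows = []
    for i in range(pool.n_clones):
        variants = ";".join(k.hgvs_pro() for k in pool.clone_variants(i))
        rows.append({"clone": i, "variants": variants, "abundance": pool.abundance[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_marginal_frequencies(pool, path: str | Path) -> None:
    """Marginal per-variant pool frequencies as TSV."""
    marg = pool.marginal_frequencies()
    pd.DataFrame(
        [
            {"variant": k.hgvs_pro(), "pos": k.pos, "ref": k.ref, "alt": k.alt,
             "frequency": f}
            for k, f in sorted(marg.items())
        ]
    ).to_csv(path, sep="\t", index=False)


CONFIG_FORMAT_VERSION = 1


def write_scoring_config(config, path: str | Path) -> None:
    """Versioned key-value capture of every scoring threshold."""
    from dataclasses import asdict

    payload = {"format_version": CONFIG_FORMAT_VERSION, **asdict(config)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_scoring_config(path: str | Path):
    from .pipeline import ScoringConfig

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.pop("format_version", None)
    if version != CONFIG_FORMAT_VERSION:
        raise MalformedInputError(f"unsupported config format version {version}")
    return ScoringConfig(**payload)


def write_evidence_report(
    scores: pd.Series,
    calib: LlrCalibration,
    thresholds: EvidenceThresholds,
    path: str | Path,
) -> None:
    """Per-variant evidence report CSV: score, LLRp, category, extrapolated."""
    from .calibration import assign_evidence

    rows = []
    for key, score in scores.items():
        hgvs = (
            VariantKey(*key).hgvs_pro() if isinstance(key, tuple) else str(key)
        )
        category, llr, extrapolated = assign_evidence(float(score), calib, thresholds)
        rows.append(
            {"variant": hgvs, "score": score, "llr": llr,
             "evidence": category, "extrapolated": extrapolated}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_calibration(
    calib: LlrCalibration,
    thresholds: EvidenceThresholds,
    path_table: str | Path,
    path_meta: str | Path,
    n_grid: int = 256,
) -> None:
    """Export an LLR calibration: a score-grid table plus a JSON sidecar."""
    lo, hi = calib.support
    grid = np.linspace(lo, hi, n_grid)
    pd.DataFrame(
        {
            "score": grid,
            "density_pos": calib.density_pos(grid),
            "density_neg": calib.density_neg(grid),
            "llr": calib.llr(grid),
        }
    ).to_csv(path_table, sep="\t", index=False)
    with open(path_meta, "w") as fh:
        json.dump(
            {
                "bandwidth_pos": calib.bandwidths[0],
                "bandwidth_neg": calib.bandwidths[1],
                "support": list(calib.support),
                "prior": thresholds.prior,
                "odds_pvst": thresholds.odds_pvst,
                "llr_cuts": thresholds.llr_cuts,
            },
            fh,
            indent=2,
        )
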