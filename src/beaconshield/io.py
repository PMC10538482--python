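"""Plain-text readers and writers: VCF, TSV, and JSON artifacts.

All outputs are diffable text.  Floats are written with 12 significant
digits so re-reads reproduce computations bit-for-bit at double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import TradeoffPoint
from .panel import AAF, BEACON, BeaconRelease, DefensePlan

FLOAT_FMT = "%.12g"


def read_vcf_carriers(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Collapse VCF genotypes to carrier indicators.

    Any non-reference allele call makes ``d_ij = 1``; missing genotypes
    count as non-carriers.  Multi-allelic records are rejected — split them
    upstream (e.g. ``bcftools norm -m-``).

    Returns ``(carriers, snv_ids, sample_ids)`` with ``snv_ids`` formatted
    ``chrom:pos:ref:alt`` (1-based positions, as in the VCF).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "normalize to biallelic records first"
            )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types)
        rows.append(((gt == 1) | (gt == 2)).astype(np.int8))
        ids.append(f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
    if not rows:
        raise ValueError(f"no variants found in {path}")
    return np.column_stack(rows), ids, samples


def read_frequencies_tsv(path) -> pd.DataFrame:
    """Reference AAF table with columns chrom, pos, ref, alt, aaf."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "aaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency TSV missing columns: {sorted(missing)}")
    return df


def write_frequencies_tsv(path, snv_ids, aafs) -> None:
    rows = []
    for sid, p in zip(snv_ids, aafs):
        parts = sid.split(":")
        chrom, pos, ref, alt = (parts + ["N", "N"])[:4] if len(parts) >= 2 else ("0", "0", "N", "N")
        rows.append((chrom, pos, ref, alt, FLOAT_FMT % p))
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "aaf"]).to_csv(
        path, sep="\t", index=False
    )


def write_carrier_matrix_tsv(path, carriers: np.ndarray, snv_ids, sample_ids=None) -> None:
    idx = sample_ids or [f"ind{i}" for i in range(carriers.shape[0])]
    pd.DataFrame(carriers, index=idx, columns=list(snv_ids)).to_csv(path, sep="\t")


def read_carrier_matrix_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.int8), list(df.columns), list(df.index)


def write_beacon_release_json(path, release: BeaconRelease, snv_ids,
                              plan: DefensePlan | None = None) -> None:
    """``{snv_id: true/false/null}`` — null marks masked SNVs."""
    x = release.x + (plan.delta if plan is not None else 0)
    masked = plan.masked if plan is not None else np.zeros(len(snv_ids), dtype=bool)
    out = {
        sid: (None if masked[j] else bool(x[j]))
        for j, sid in enumerate(snv_ids)
    }
    Path(path).write_text(json.dumps(out, indent=1) + "\n")


def write_plan_json(path, plan: DefensePlan, snv_ids=None, point: TradeoffPoint | None = None) -> None:
    ids = list(snv_ids) if snv_ids is not None else [f"snv{j}" for j in range(plan.m)]
    doc = {
        "mode": plan.mode,
        "m": plan.m,
        "masked": [ids[j] for j in plan.masked_indices],
        "noise": {
            ids[j]: float(FLOAT_FMT % plan.delta[j])
            for j in np.flatnonzero(plan.delta != 0)
        },
    }
    if point is not None:
        doc["result"] = {
            "method": point.method, "w": point.w, "alpha": point.alpha,
            "utility_pct": float(FLOAT_FMT % point.utility_pct),
            "privacy_pct": float(FLOAT_FMT % point.privacy_pct),
            "objective": float(FLOAT_FMT % point.objective),
        }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_plan_json(path, snv_ids=None) -> DefensePlan:
    doc = json.loads(Path(path).read_text())
    m = doc["m"]
    ids = list(snv_ids) if snv_ids is not None else [f"snv{j}" for j in range(m)]
    index = {sid: j for j, sid in enumerate(ids)}
    masked = np.zeros(m, dtype=bool)
    for sid in doc["masked"]:
        masked[index[sid]] = True
    delta = np.zeros(m)
    for sid, v in doc["noise"].items():
        delta[index[sid]] = v
    return DefensePlan(m=m, mode=doc["mode"], masked=masked, delta=delta)


def write_scores_tsv(path, individual_ids, scores, claimed, protected) -> None:
    pd.DataFrame(
        {
            "individual_id": individual_ids,
            "score": [FLOAT_FMT % s for s in scores],
            "claimed": np.asarray(claimed, dtype=int),
            "protected": np.asarray(protected, dtype=int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_frontier_tsv(path, points: list[TradeoffPoint]) -> None:
    pd.DataFrame(
        {
            "method": [p.method for p in points],
            "w": [p.w for p in points],
            "alpha": [p.alpha for p in points],
            "utility_pct": [FLOAT_FMT % p.utility_pct for p in points],
            "privacy_pct": [FLOAT_FMT % p.privacy_pct for p in points],
            "U": [FLOAT_FMT % p.objective for p in points],
            "seed": [("" if p.seed is None else p.seed) for p in points],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ld_map_tsv(path, ld) -> None:
    rows = [
        (j, k, FLOAT_FMT % ld.coefficients[(j, int(k))])
        for j, nbrs in sorted(ld.neighbors.items())
        for k in nbrs
    ]
    pd.DataFrame(rows, columns=["snv", "neighbor", "ld"]).to_csv(path, sep="\t", index=False)
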