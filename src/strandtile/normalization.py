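"""Probe-effect and background correction against a genomic-DNA channel.

Hybridization efficiency varies by probe sequence (the "probe effect"); a
genomic-DNA hybridization measures each probe at constant copy number, so
dividing the RNA channel by the gDNA channel cancels the per-probe
multiplicative effect.  Background is then anchored at zero by subtracting,
per sample, the median log2 ratio over uniquely-mapping probes whose
footprint overlaps no annotated CDS on either strand.

Only uniquely-mapping probes enter the output.  The transformation is
exactly invariant to a global rescaling of a sample's RNA channel (the shift
is absorbed by the background median) and strictly increasing in the raw
intensity for fixed gDNA and background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import GeneModel, IntensityMatrix, Probe, ProbeMap


@dataclass
class NormalizedSignal:
    """Log2 normalized intensity, unique probes x RNA samples.

    ``background`` records the per-sample median offset b_c that was
    subtracted; ``n_excluded`` counts probes dropped for non-positive gDNA.
    """

    values: pd.DataFrame
    background: dict[str, float]
    n_excluded: int = 0

    def report(self) -> dict:
        return {
            "samples": list(self.values.columns),
            "n_probes": int(self.values.shape[0]),
            "background_offsets": {k: float(v) for k, v in self.background.items()},
            "n_excluded_probes": int(self.n_excluded),
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        df = self.values.copy()
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.report(), indent=2)
        )

    @classmethod
    def read(cls, path: str | Path) -> "NormalizedSignal":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="probe_id")
        report = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            values=values,
            background=report["background_offsets"],
            n_excluded=report["n_excluded_probes"],
        )


def _merged_cds_intervals(genes: Iterable[GeneModel]) -> dict[str, np.ndarray]:
    """Per chromosome, merged CDS intervals from both strands, as (m, 2) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.cds_start, g.cds_end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out)
    return merged


def non_cds_probe_ids(probes: Sequence[Probe], genes: Iterable[GeneModel]) -> list[str]:
    """Uniquely-mapping probes whose footprint overlaps no CDS on either strand."""
    merged = _merged_cds_intervals(genes)
    keep: list[str] = []
    for p in probes:
        if not p.unique:
            continue
        ivs = merged.get(p.chrom)
        if ivs is None:
            keep.append(p.probe_id)
            continue
        # overlap iff some interval with start < p.end and end > p.start
        idx = np.searchsorted(ivs[:, 0], p.end)  # intervals starting before p.end
        if idx == 0 or ivs[:idx, 1].max() <= p.start:
            keep.append(p.probe_id)
    return keep


def normalize_to_gdna(
    rna: IntensityMatrix,
    gdna: str | pd.Series | None,
    probes: ProbeMap,
    genes: Iterable[GeneModel],
    background_probe_ids: Sequence[str] | None = None,
) -> NormalizedSignal:
    """log2(RNA / gDNA) per unique probe, background-anchored at zero.

    Parameters
    ----------
    gdna
        Name of the gDNA-channel column, a Series of gDNA intensities, or
        None to use the matrix's single gDNA-channel sample.
    background_probe_ids
        Optional explicit background probe set, overriding the non-CDS rule
        (needed when the annotation leaves no CDS-free probes).
    """
    if gdna is None:
        gdna = rna.gdna_sample()
    if isinstance(gdna, str):
        gdna_values = rna.values[gdna]
        rna_samples = [s for s in rna.rna_samples() if s != gdna]
    else:
        gdna_values = gdna
        rna_samples = rna.rna_samples()

    unique_ids = pd.Index(
        dict.fromkeys(p.probe_id for p in probes.unique_probes())
    )
    unique_ids = unique_ids.intersection(rna.values.index)
    gdna_values = gdna_values.reindex(unique_ids)

    bad = ~(gdna_values > 0) | gdna_values.isna()
    n_excluded = int(bad.sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} probes with non-positive/missing gDNA values"
        )
        unique_ids = unique_ids[~bad.to_numpy()]
        gdna_values = gdna_values.loc[unique_ids]

    ratios = np.log2(
        rna.values.loc[unique_ids, rna_samples].div(gdna_values, axis=0)
    )

    genes = list(genes)
    if background_probe_ids is None:
        probe_subset = [p for p in probes.unique_probes() if p.probe_id in set(unique_ids)]
        background_probe_ids = non_cds_probe_ids(probe_subset, genes)
    background_probe_ids = [b for b in background_probe_ids if b in set(unique_ids)]
    if not background_probe_ids:
        raise ValueError(
            "no CDS-free unique probes available for background correction; "
            "supply background_probe_ids explicitly"
        )

    offsets = {
        c: float(ratios.loc[background_probe_ids, c].median()) for c in rna_samples
    }
    normalized = ratios.sub(pd.Series(offsets), axis=1)
    return NormalizedSignal(
        values=normalized, background=offsets, n_excluded=n_excluded
    )
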