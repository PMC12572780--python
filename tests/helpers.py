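"""Shared builders for small in-memory fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from supergene_scan.io_formats import MISSING, Gene, GeneSet, GenotypeMatrix, Transcript


def make_gm(
    calls,
    positions=None,
    chrom="chr1",
    qual=60.0,
    depths=None,
    sample_ids=None,
    ref="A",
    alt="G",
):
    """GenotypeMatrix from a (samples x sites) nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = (np.arange(n_sites) + 1) * 100
    chroms = [chrom] * n_sites if isinstance(chrom, str) else list(chrom)
    quals = [qual] * n_sites if np.isscalar(qual) else list(qual)
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=int),
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
            "qual": quals,
        }
    )
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        sites=sites,
        calls=calls,
        depths=None if depths is None else np.asarray(depths),
    )


def make_gene(gene_id, chrom, cds_by_transcript, strand="+"):
    """Gene with transcripts given as {transcript_id: [(start, end), ...]}."""
    return Gene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=tuple(
            Transcript(transcript_id=tid, cds=tuple(tuple(iv) for iv in ivs))
            for tid, ivs in cds_by_transcript.items()
        ),
    )


def swap_ref_alt(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Relabel ref/alt at every site: 0 <-> 2, het and MISSING unchanged."""
    calls = gm.calls.copy()
    calls[gm.calls == 0] = 2
    calls[gm.calls == 2] = 0
    sites = gm.sites.copy()
    sites[["ref", "alt"]] = sites[["alt", "ref"]].to_numpy()
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids), sites=sites, calls=calls, depths=gm.depths
    )
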