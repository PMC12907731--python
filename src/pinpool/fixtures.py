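"""Fixture generation: small, fully simulated experiment directories.

Profiles produce everything the pipeline consumes — reference FASTA, sample
sheet, per-pool VCFs with synthetic annotations, and truth tables — sized to
run the full decode/filter/evaluate cycle in seconds. Regeneration with the
same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import pandas as pd

from .simulate import SimConfig, simulate_matrix
from .vcfio import write_calls_vcf, write_keys_vcf, write_reference_fasta, write_sample_sheet

__all__ = ["PROFILES", "make_fixtures"]

PROFILES: dict[str, SimConfig] = {
    "tiny-3x3": SimConfig(n_rows=3, n_cols=3, n_sites=60, allelic_coverage=30.0,
                          fp_site_rate=5.0, site_spacing=25),
    "default-10x10": SimConfig(),  # the reference study conditions
}


def make_fixtures(profile: str, seed: int, out_dir) -> Path:
    """Generate a complete small input directory for one profile.

    Writes ``reference.fa(.fai)``, ``sample_sheet.tsv``, ``pools/<pool>.vcf``,
    ``truth/truth_sites.tsv``, ``truth/labels.tsv``,
    ``truth/private_variants.tsv`` and a frozen ``sim_config.json``.
    """
    if profile not in PROFILES:
        raise KeyError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    config = replace(PROFILES[profile], seed=seed)
    out = Path(out_dir)
    (out / "pools").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)

    truth, layout, row_pools, col_pools, labels = simulate_matrix(config)
    contigs = {config.contig: len(truth.reference.seq)}

    write_reference_fasta(truth.reference, out / "reference.fa")
    write_sample_sheet(layout, out / "sample_sheet.tsv")
    for pool in row_pools + col_pools:
        write_calls_vcf(
            pool.calls.values(),
            out / "pools" / f"{pool.pool_id}.vcf",
            contigs=contigs,
            provenance=f"pinpool simulate profile={profile} seed={seed}",
        )

    site_rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "vtype": vt, "allele_frequency": af}
        for k, af, vt in truth.site_table
    ]
    pd.DataFrame(site_rows).to_csv(out / "truth" / "truth_sites.tsv", sep="\t", index=False)

    label_rows = [
        {"pool_id": pid, "chrom": k.chrom, "pos": k.pos, "ref": k.ref,
         "alt": k.alt, "label": lab}
        for pid, d in labels.items()
        for k, lab in sorted(d.items())
    ]
    pd.DataFrame(label_rows).to_csv(out / "truth" / "labels.tsv", sep="\t", index=False)

    private_rows = [
        {"sample_id": s, "chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt}
        for s, keys in truth.private_variants().items()
        for k in sorted(keys)
    ]
    pd.DataFrame(
        private_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
    ).to_csv(out / "truth" / "private_variants.tsv", sep="\t", index=False)

    # theoretical (noiseless) pool sets, for labeling and pool-level evaluation
    (out / "truth" / "theoretical_pools").mkdir(exist_ok=True)
    rsets, csets = truth.pool_variant_sets(layout)
    for pid, keys in {**rsets, **csets}.items():
        write_keys_vcf(keys, out / "truth" / "theoretical_pools" / f"{pid}.vcf",
                       contigs=contigs, provenance=f"pinpool truth pools seed={seed}")

    with open(out / "sim_config.json", "w") as fh:
        json.dump({"profile": profile, **asdict(config)}, fh, indent=2, sort_keys=True)
    return out
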