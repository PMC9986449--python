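import pandas as pd
import pytest

from rgenekit import simulate


@pytest.fixture(scope="session")
def small_annotation():
    cfg = simulate.SimConfig(seed=42, n_base_genes=60, ase_pairs=3)
    return cfg, simulate.simulate_annotation(cfg)


@pytest.fixture(scope="session")
def small_counts(small_annotation):
    cfg, ann = small_annotation
    return simulate.simulate_counts(cfg, ann)


@pytest.fixture()
def annotation_files(tmp_path, small_annotation):
    """Annotation written to disk for path-based loaders."""
    _, ann = small_annotation
    gff = tmp_path / "ann.gff3"
    dom = tmp_path / "domains.tsv"
    fa = tmp_path / "cds.fasta"
    gff.write_text(ann.gff3)
    dom.write_text(ann.domain_tsv)
    fa.write_text(ann.cds_fasta)
    return {"gff": gff, "domains": dom, "cds": fa, "truth": ann.truth}


def make_de_table(rows):
    """Allele-level DE table from (feature_id, log2fc, fdr) triples; DE and
    direction follow the default thresholds."""
    recs = []
    for fid, lfc, fdr in rows:
        is_de = fdr < 0.05 and abs(lfc) >= 1.0
        recs.append(
            {
                "feature_id": fid,
                "log2fc": lfc,
                "fdr": fdr,
                "p_value": fdr,
                "is_de": is_de,
                "direction": ("up" if lfc > 0 else "down") if is_de else "none",
            }
        )
    return pd.DataFrame(recs)
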