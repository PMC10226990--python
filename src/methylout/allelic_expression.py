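"""Allelic transcript imbalance from full-length cDNA read counts.

At a heterozygous SNV inside a transcript, balanced biallelic expression
puts the minor allele near 50% of informative reads.  Promoter
hypermethylation silencing one allele drags the minor-allele fraction down;
a record *deviates* when the minor fraction falls strictly below the ratio
bound (default 0.45, i.e. beyond a 45:55 split).  Carriers of the linked
hyper-mCpG tile are summarized against non-carrier controls.
"""

from __future__ import annotations

import pandas as pd


def allelic_ratio(n_allele1: int, n_allele2: int, min_total: int = 10,
                  ratio_bound: float = 0.45) -> tuple[float | None, bool | None]:
    """(minor-allele fraction, deviates flag) for one count record.

    Records with total reads < ``min_total`` are uninformative and return
    (None, None).  The deviation test is strict: a minor fraction exactly at
    the bound does not deviate.
    """
    if n_allele1 < 0 or n_allele2 < 0:
        raise ValueError("read counts must be non-negative")
    total = n_allele1 + n_allele2
    if total < min_total:
        return None, None
    minor = min(n_allele1, n_allele2) / total
    return minor, minor < ratio_bound


def summarize_carriers(records: pd.DataFrame, min_total: int = 10,
                       ratio_bound: float = 0.45) -> pd.DataFrame:
    """Deviation rates for carrier vs control groups.

    ``records`` needs columns n_allele1, n_allele2 and group ('carrier' or
    'control').  Returns one row per group with n_informative, n_deviating,
    fraction and integer percent; groups with zero informative records get
    NaN fraction and None percent.
    """
    rows = []
    for group in ("carrier", "control"):
        sub = records[records["group"] == group]
        n_inf = 0
        n_dev = 0
        for rec in sub.itertuples(index=False):
            minor, dev = allelic_ratio(int(rec.n_allele1), int(rec.n_allele2),
                                       min_total=min_total, ratio_bound=ratio_bound)
            if minor is None:
                continue
            n_inf += 1
            n_dev += int(dev)
        rows.append({
            "group": group,
            "n_informative": n_inf,
            "n_deviating": n_dev,
            "fraction": n_dev / n_inf if n_inf else float("nan"),
            "percent": int(round(100.0 * n_dev / n_inf)) if n_inf else None,
        })
    return pd.DataFrame(rows)


def read_allelic_counts(path) -> pd.DataFrame:
    """Read a counts TSV: sample, region_id, chrom, pos, ref, alt, n_ref,
    n_alt, linked_tile_id (empty when unlinked)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns={"n_ref": "n_allele1", "n_alt": "n_allele2"})
    return df
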