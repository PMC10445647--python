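import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from finecoloc.finemap import CredibleSet, LocusData, make_variant_ids

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_locus(z, ld=None, n=10_000, chrom="chr1", pos0=1000):
    """Hand-built locus: z-scores plus optional LD (identity by default)."""
    z = np.asarray(z, dtype=float)
    m = z.size
    ld = np.eye(m) if ld is None else np.asarray(ld, dtype=float)
    se = np.full(m, 0.01)
    pos = pos0 + 10 * np.arange(m)
    return LocusData(
        variant_ids=make_variant_ids(chrom, pos, ["A"] * m, ["G"] * m),
        chrom=np.repeat(chrom, m),
        pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        beta=z * se,
        se=se,
        n=np.full(m, n),
        maf=np.full(m, 0.3),
        ld=ld,
        z=z,
    )


def make_cs(cs_id, ids, pips, coverage=0.95):
    """Hand-built credible set from parallel id/PIP lists."""
    pips = np.asarray(pips, dtype=float)
    order = np.argsort(-pips, kind="stable")
    ids = np.asarray(ids, dtype=object)[order]
    pips = pips[order]
    return CredibleSet(
        cs_id=cs_id,
        member_ids=ids,
        pip=pips,
        signal_pip_total=float(pips.sum()),
        coverage_achieved=coverage,
        lead_id=str(ids[0]),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230809)
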