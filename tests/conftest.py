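import numpy as np
import pytest

from tempodose import SampleAnnotation, FeatureAnnotation, TimeCourseExperiment
from tempodose.spline_basis import build_basis, place_knots


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design_4x8():
    """Line-major 4-line x 8-time design with a K=2 thin-plate basis."""
    n, T = 4, 8
    times = np.tile(np.arange(1.0, T + 1.0), n)
    lines = np.repeat(np.arange(n), T)
    X = np.zeros((n * T, n))
    X[np.arange(n * T), lines] = 1.0
    basis = build_basis(times, place_knots(times, 2))
    return {"n": n, "T": T, "N": n * T, "times": times, "lines": lines,
            "X": X, "basis": basis}


@pytest.fixture
def design_2x6():
    n, T = 2, 6
    times = np.tile(np.arange(1.0, T + 1.0), n)
    lines = np.repeat(np.arange(n), T)
    X = np.zeros((n * T, n))
    X[np.arange(n * T), lines] = 1.0
    basis = build_basis(times, place_knots(times, 2))
    return {"n": n, "T": T, "N": n * T, "times": times, "lines": lines,
            "X": X, "basis": basis}


def make_experiment(expr, cn=None, n_lines=2, family="gaussian"):
    """Wrap matrices in a TimeCourseExperiment with a synthetic annotation."""
    p, N = expr.shape
    T = N // n_lines
    samples = [
        SampleAnnotation(f"s{i}_{t}", f"line{i}", float(t + 1))
        for i in range(n_lines) for t in range(T)
    ]
    features = [
        FeatureAnnotation(f"f{j:04d}", "chr1", j * 1000, j * 1000 + 500, j)
        for j in range(p)
    ]
    return TimeCourseExperiment(expression=expr, copy_number=cn, samples=samples,
                                features=features, family=family)


@pytest.fixture
def tiny_files(tmp_path):
    """Write a 3-feature x 4-sample toy dataset to TSV files."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "feature_id\ts1\ts2\ts3\ts4\n"
        "fA\t1.0\t2.0\t3.0\t4.0\n"
        "fB\t0.5\t0.6\t0.7\t0.8\n"
        "fC\t-1.0\t0.0\t1.0\t2.0\n")
    cn = tmp_path / "cn.tsv"
    cn.write_text(
        "feature_id\ts1\ts2\ts3\ts4\n"
        "fA\t0.0\t0.1\t0.2\t0.3\n"
        "fB\t0.0\t0.0\t0.0\t0.0\n"
        "fC\t-0.5\t-0.5\t0.5\t0.5\n")
    samp = tmp_path / "samples.tsv"
    samp.write_text(
        "sample_id\tline\ttime\n"
        "s1\tA\t1\ns2\tA\t2\ns3\tA\t3\ns4\tA\t4\n")
    feat = tmp_path / "features.tsv"
    feat.write_text(
        "feature_id\tchromosome\tstart\tend\n"
        "fA\tchr1\t100\t200\n"
        "fB\tchr1\t300\t400\n"
        "fC\tchr2\t100\t200\n")
    return {"expr": expr, "cn": cn, "samples": samp, "features": feat,
            "dir": tmp_path}
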