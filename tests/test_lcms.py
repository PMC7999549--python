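"""EIC extraction, peak integration, library matching, molar normalisation."""

import base64
import struct

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muroquant import murolib, synth
from muroquant.lcms import (
    CentroidedRun,
    EICTrace,
    extract_eic,
    integrate_peak,
    match_run,
    normalize_molar,
)


def _run_from_rows(rows):
    """rows: (rt, mz, intensity) triplets."""
    df = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    return CentroidedRun.from_peak_table(df)


# --- extraction ------------------------------------------------------------


def test_eic_empty_window_is_all_zeros():
    run = _run_from_rows([(0.0, 500.0, 10.0), (1.0, 500.0, 20.0)])
    trace = extract_eic(run, 800.0, 10.0)
    assert np.all(trace.intensities == 0)
    assert trace.times.size == 2


def test_eic_picks_up_exact_match_and_sums_isobars():
    run = _run_from_rows(
        [
            (0.0, 500.0, 10.0),
            (1.0, 500.0001, 7.0),
            (1.0, 499.9999, 5.0),
            (1.0, 500.1, 99.0),  # 200 ppm away: outside window
        ]
    )
    trace = extract_eic(run, 500.0, 10.0)
    # brute-force oracle: sum everything within the ppm window per spectrum
    lo, hi = 500.0 * (1 - 1e-5), 500.0 * (1 + 1e-5)
    expected = [10.0, 7.0 + 5.0]
    assert trace.intensities.tolist() == expected
    assert lo < 499.9999 < 500.0001 < hi < 500.1


def test_eic_requires_positive_tolerance():
    run = _run_from_rows([(0.0, 500.0, 1.0)])
    with pytest.raises(ValueError):
        extract_eic(run, 500.0, 0.0)


def test_run_rejects_unsorted_times_and_negative_intensity():
    with pytest.raises(ValueError):
        CentroidedRun.from_spectra(
            [(1.0, [500.0], [1.0]), (0.5, [500.0], [1.0])]
        )
    with pytest.raises(ValueError):
        CentroidedRun.from_spectra([(0.0, [500.0], [-1.0])])
    with pytest.raises(ValueError):
        CentroidedRun.from_spectra([])


# --- integration -----------------------------------------------------------


def test_integrate_flat_trace_is_zero_after_baseline():
    t = np.linspace(0, 5, 51)
    trace = EICTrace(500.0, 10.0, t, np.full(51, 7.0))
    assert integrate_peak(trace, (1.0, 4.0)) == 0.0


def test_integrate_triangle_matches_closed_form():
    t = np.linspace(0, 2, 2001)
    y = np.maximum(0.0, 1.0 - np.abs(t - 1.0)) * 50.0  # height 50, base 2
    trace = EICTrace(500.0, 10.0, t, y)
    assert integrate_peak(trace, (0.0, 2.0)) == pytest.approx(50.0, rel=1e-4)


def test_integrate_window_outside_range_errors():
    trace = EICTrace(500.0, 10.0, np.array([0.0, 1.0]), np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        integrate_peak(trace, (5.0, 6.0))
    with pytest.raises(ValueError):
        integrate_peak(trace, (1.0, 0.5))
    assert integrate_peak(trace, (0.0, 1.0)) == 0.0


# --- matching --------------------------------------------------------------


def test_match_recovers_three_species_noiselessly(published_quant, published_library):
    quant = published_quant.iloc[:3].copy()
    quant["molar_percent"] = 100 * quant["area"] / quant["area"].sum()
    run, _ = synth.gen_lcms_run(
        quant, published_library, ppm_noise_sd=0.0, peak_cv=0.0, seed=0
    )
    idents = match_run(run, published_library, tolerance_ppm=10.0)
    found = {i.name: i for i in idents}
    assert set(found) == set(quant["name"])
    for _, row in quant.iterrows():
        generated = 1e4 * row["molar_percent"]
        assert found[row["name"]].area == pytest.approx(generated, rel=0.01)
        assert found[row["name"]].mass_error_ppm == pytest.approx(0.0, abs=1e-6)


def test_tight_tolerance_against_large_mass_noise_finds_nothing(
    published_quant, published_library
):
    run, _ = synth.gen_lcms_run(
        published_quant, published_library, ppm_noise_sd=20.0, peak_cv=0.0, seed=0
    )
    idents = match_run(run, published_library, tolerance_ppm=0.1)
    assert idents == []


def test_species_separated_in_mass_do_not_cross_match():
    lib = [
        murolib.make_record(murolib.MuropeptideComposition(1, (4,), 0)),
        murolib.make_record(murolib.MuropeptideComposition(1, (3,), 0)),
    ]
    quant = pd.DataFrame(
        {"name": [r.name for r in lib], "area": [1.0, 2.0], "molar_percent": [40.0, 60.0]}
    )
    run, rts = synth.gen_lcms_run(quant, lib, ppm_noise_sd=0.0, peak_cv=0.0, seed=0)
    idents = match_run(run, lib, tolerance_ppm=10.0)
    assert [i.name for i in idents] == sorted(r.name for r in lib)
    for ident in idents:
        assert ident.apex_rt == pytest.approx(rts[ident.name], abs=0.05)


def test_match_requires_library():
    run = _run_from_rows([(0.0, 500.0, 1.0)])
    with pytest.raises(ValueError):
        match_run(run, [])


# --- normalisation ---------------------------------------------------------


def test_normalize_molar_basic_and_errors():
    df = pd.DataFrame({"name": ["a", "b", "c"], "area": [1.0, 1.0, 2.0]})
    out = normalize_molar(df)
    assert out["molar_percent"].tolist() == [25.0, 25.0, 50.0]
    single = normalize_molar(pd.DataFrame({"name": ["x"], "area": [3.0]}))
    assert single["molar_percent"].tolist() == [100.0]
    with pytest.raises(ValueError):
        normalize_molar(pd.DataFrame({"name": ["x"], "area": [0.0]}))
    with pytest.raises(ValueError):
        normalize_molar(pd.DataFrame({"name": [], "area": []}))


@settings(derandomize=True, max_examples=30)
@given(
    areas=st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=8),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_molar_percentages_scale_invariant_and_sum_to_100(areas, scale):
    names = [f"s{i}" for i in range(len(areas))]
    base = normalize_molar(pd.DataFrame({"name": names, "area": areas}))
    scaled = normalize_molar(
        pd.DataFrame({"name": names, "area": [a * scale for a in areas]})
    )
    assert base["molar_percent"].sum() == pytest.approx(100.0, abs=1e-6)
    assert np.allclose(base["molar_percent"], scaled["molar_percent"], rtol=1e-9)


def test_round_trip_with_acquisition_noise(published_quant, published_library):
    """ppm 5 / per-scan height CV 5%: every species within 1.5 points."""
    run, _ = synth.gen_lcms_run(
        published_quant, published_library, ppm_noise_sd=5.0, peak_cv=0.05, seed=0
    )
    quant = normalize_molar(match_run(run, published_library, tolerance_ppm=10.0))
    merged = quant.merge(published_quant, on="name", suffixes=("_rec", "_true"))
    assert len(merged) == len(published_quant)
    err = (merged["molar_percent_rec"] - merged["molar_percent_true"]).abs()
    assert err.max() < 1.5


# --- mzML ------------------------------------------------------------------


def _encode(values):
    raw = struct.pack("<" + "d" * len(values), *values)
    return base64.b64encode(raw).decode()


def _mzml_document(spectra):
    chunks = []
    for i, (rt, mzs, ints) in enumerate(spectra):
        chunks.append(f"""
  <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
      <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
      <scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}"
                 unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
      </scan>
    </scanList>
    <binaryDataArrayList count="2">
      <binaryDataArray encodedLength="{len(_encode(mzs))}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
        <binary>{_encode(mzs)}</binary>
      </binaryDataArray>
      <binaryDataArray encodedLength="{len(_encode(ints))}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
        <binary>{_encode(ints)}</binary>
      </binaryDataArray>
    </binaryDataArrayList>
  </spectrum>""")
    body = "".join(chunks)
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="UO" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <run id="synthetic_run">
    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">{body}
    </spectrumList>
  </run>
</mzML>
"""


def test_mzml_reading_matches_in_memory_run(tmp_path):
    spectra = [
        (0.1, [500.0, 941.4149], [5.0, 100.0]),
        (0.2, [941.4149], [250.0]),
        (0.3, [941.4149, 1200.0], [90.0, 1.0]),
    ]
    path = tmp_path / "synthetic_run.mzml"
    path.write_text(_mzml_document(spectra))
    run = CentroidedRun.from_mzml(path)
    assert run.n_spectra == 3
    assert run.times.tolist() == pytest.approx([0.1, 0.2, 0.3])
    trace = extract_eic(run, 941.4149, 10.0)
    assert trace.intensities.tolist() == [100.0, 250.0, 90.0]
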