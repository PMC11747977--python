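import numpy as np
import pytest

from seizdyn import io_preprocess as iop
from seizdyn import synthetic as syn
from seizdyn._edf import write_edf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def edf_recording(tmp_path_factory):
    """Writer-generated EDF fixture: 32 ch, 600 s @ 512 Hz, one annotation."""
    d = tmp_path_factory.mktemp("edf")
    gen = np.random.default_rng(7)
    n_ch, fs, dur = 32, 512, 600
    data = gen.standard_normal((n_ch, fs * dur)) * 30.0
    path = d / "rec.edf"
    write_edf(path, data, fs, [f"EEG{i:02d}" for i in range(n_ch)])
    ann = d / "ann.csv"
    ann.write_text(
        "patient_id,seizure_id,onset_s,offset_s,vigilance,classification\n"
        "P001,sz1,100,200,Awake,FIAS\n"
    )
    return {"edf": path, "ann": ann, "data": data, "fs": fs}


@pytest.fixture(scope="session")
def snic_flc_source():
    spec = syn.SeizureSimSpec(
        syn.BifurcationType("onset", "SNIC"),
        syn.BifurcationType("offset", "FLC"),
        duration_s=40.0,
        seed=11,
    )
    return syn.simulate_source(spec)


@pytest.fixture(scope="session")
def suph_source():
    spec = syn.SeizureSimSpec(
        syn.BifurcationType("onset", "SupH"),
        syn.BifurcationType("offset", "SupH"),
        duration_s=40.0,
        seed=12,
    )
    return syn.simulate_source(spec)


@pytest.fixture()
def short_segment(rng):
    # pink (1/f) background: the spectral profile preprocessing sees in EEG
    fs = 512.0
    n = int(fs * 160)
    white = rng.standard_normal((12, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    data = np.fft.irfft(spec * f**-0.5, n=n, axis=1)
    data *= 20.0 / data.std(axis=1, keepdims=True)
    return iop.Segment(
        data=data, fs=fs, t0_s=0.0, core_interval=(40.0, 120.0), role="seizure",
        channel_names=[f"ch{i}" for i in range(12)],
    )
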