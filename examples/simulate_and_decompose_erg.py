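"""Simulate one animal's multi-flash ERG session and decompose it.

Builds the default dark- plus light-adapted flash family (4 kHz, 640 ms
sweeps) with known ground-truth parameters, runs the P3/P2/pSTR
decomposition, and compares what the pipeline measures with what the
generator planted.
"""

from dataclasses import replace

from retinerg import ergdecomp, ergsim

# noiseless, unfiltered: the decomposition should recover the generator
# parameters almost exactly
acc = replace(ergsim.DEFAULT_ACCESSORY, noise_sd=0.0, acquisition_band=None)
family = ergsim.generate_family(ergsim.default_protocol(), acc=acc, seed=0)
result = ergdecomp.decompose(family)

planted = {
    "rod RmP3 (uV)": (ergsim.DEFAULT_ROD_P3.rm_p3, result.rod_p3.params.rm_p3),
    "rod Vmax (uV)": (ergsim.DEFAULT_ROD_P2.vmax, result.rod_p2.vmax),
    "rod K (cd.s/m2)": (ergsim.DEFAULT_ROD_P2.k, result.rod_p2.k),
    "cone RmP3 (uV)": (ergsim.DEFAULT_CONE_P3.rm_p3,
                       result.cone_p3.params.rm_p3),
    "cone Vmax (uV)": (ergsim.DEFAULT_CONE_P2.vmax, result.cone_p2.vmax),
    "pSTR (uV)": (ergsim.DEFAULT_ACCESSORY.str_amplitude,
                  result.pstr.amplitude),
}

print(f"{'endpoint':18s} {'planted':>10s} {'measured':>10s} {'err %':>7s}")
for name, (truth, measured) in planted.items():
    print(f"{name:18s} {truth:10.3f} {measured:10.3f} "
          f"{100 * abs(measured - truth) / truth:7.2f}")
print("\nEach row is one functional endpoint: photoreceptor saturated "
      "amplitude (RmP3), bipolar-cell saturated b-wave amplitude (Vmax), "
      "semi-saturation energy (K) and the ganglion-cell pSTR peak. "
      "Sub-percent errors show the decomposition inverts the generator.")
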