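# Default phenotype band tables, v2.
#
# Three middle-ear phenotypes, each a list of Raman bands
# (center cm^-1, amplitude in detector counts, fwhm cm^-1, line shape)
# over a broad autofluorescence baseline. Sharp mineral / ring modes are
# Lorentzian with fwhm 7-16 cm^-1; the amide-I envelope is broader.
#
# The baseline polynomial is identical across phenotypes: tissue
# autofluorescence is a nuisance that varies specimen to specimen, not a
# class marker, so class information lives in the bands alone.
#
# Cholesteatoma and non-mineralized myringosclerosis share the same
# protein (keratin/collagen) band set, the latter at ~55% amplitude plus
# faint mineral traces at 5% of the mineralized amplitudes; with
# specimen-level band-amplitude variability of comparable size the two
# classes genuinely overlap, while the mineralized phosphate markers
# remain distinctive.
#
# Mineralized myringosclerosis: apatite phosphate modes. The 960 band is
# the nu1(PO4) symmetric stretch; its table values are the pure-apatite
# limit. Lattice substitution (substitution_degree d in [0,1]) broadens
# 960, scales the nu3-region 1044 amplitude by d, and scales the resolved
# 948 nu1 shoulder by (1 - d), so at d=0 the pure-apatite doublet is
# resolved and 1044 is absent.
version: 2
phenotypes:
  cholesteatoma:
    gross_label: cholesteatoma
    baseline_coefficients: [1.0, 0.8, -0.8, 0.12]
    baseline_scale: 800.0
    bands:
      - {center: 956.0,  amplitude: 60.0,  fwhm: 12.0, shape: lorentzian}
      - {center: 1005.0, amplitude: 220.0, fwhm: 9.0,  shape: lorentzian}
      - {center: 1032.0, amplitude: 90.0,  fwhm: 11.0, shape: lorentzian}
      - {center: 1128.0, amplitude: 70.0,  fwhm: 12.0, shape: lorentzian}
      - {center: 1447.0, amplitude: 260.0, fwhm: 18.0, shape: lorentzian}
      - {center: 1654.0, amplitude: 300.0, fwhm: 24.0, shape: gaussian}
      - {center: 1680.0, amplitude: 110.0, fwhm: 22.0, shape: gaussian}
  mineralized_myringosclerosis:
    gross_label: myringosclerosis
    baseline_coefficients: [1.0, 0.8, -0.8, 0.12]
    baseline_scale: 800.0
    substitution_degree: 0.7
    substitution_broadening: 0.8
    bands:
      - {center: 748.0,  amplitude: 80.0,  fwhm: 12.0, shape: lorentzian}
      - {center: 948.0,  amplitude: 130.0, fwhm: 7.0,  shape: lorentzian}
      - {center: 960.0,  amplitude: 420.0, fwhm: 10.0, shape: lorentzian}
      - {center: 1044.0, amplitude: 360.0, fwhm: 16.0, shape: lorentzian}
      - {center: 1447.0, amplitude: 60.0,  fwhm: 18.0, shape: lorentzian}
      - {center: 1654.0, amplitude: 70.0,  fwhm: 24.0, shape: gaussian}
  nonmineralized_myringosclerosis:
    gross_label: myringosclerosis
    baseline_coefficients: [1.0, 0.8, -0.8, 0.12]
    baseline_scale: 800.0
    bands:
      # the cholesteatoma protein band set at ~70% amplitude — one
      # specimen-effect sd below it, so the two protein phenotypes
      # overlap heavily; the 956 CH2 rock is a keratin feature and
      # stays cholesteatoma-specific
      - {center: 1005.0, amplitude: 154.0, fwhm: 9.0,  shape: lorentzian}
      - {center: 1032.0, amplitude: 63.0,  fwhm: 11.0, shape: lorentzian}
      - {center: 1128.0, amplitude: 49.0,  fwhm: 12.0, shape: lorentzian}
      - {center: 1447.0, amplitude: 182.0, fwhm: 18.0, shape: lorentzian}
      - {center: 1654.0, amplitude: 210.0, fwhm: 24.0, shape: gaussian}
      - {center: 1680.0, amplitude: 77.0,  fwhm: 22.0, shape: gaussian}
      # faint mineral traces at margins: 5% of the mineralized amplitudes
      - {center: 960.0,  amplitude: 21.0,  fwhm: 12.0, shape: lorentzian}
      - {center: 1048.0, amplitude: 18.0,  fwhm: 16.0, shape: lorentzian}
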