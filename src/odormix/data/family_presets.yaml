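# Preset family models. cos_alpha is never stored: it is derived from the
# mixture slope (cos_alpha = 2*slope^2 - 1) at load time.
# The member lists cover the odorants whose mixtures follow the family
# pattern; hydroxyl-bearing esters (n-butyl acrylate, vinyl acetate) are
# registry entries but not preset members because their mixtures deviate.
aldehydes:
  k: 5.6
  b: -5.6
  slope: 0.62
  members: [Acetaldehyde, Propionaldehyde, n-Butyraldehyde]
  oirs:
    base_concentration: 10.0
    ratio: 2.0
    n_levels: 12
esters:
  k: 1.4
  b: -2.7
  slope: 0.79
  members: [Ethyl acetate, Butyl acetate, Ethyl butyrate]
  oirs:
    base_concentration: 12.0
    ratio: 2.0
    n_levels: 8
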