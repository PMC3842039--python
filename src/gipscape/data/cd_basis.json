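{
  "comment": "Synthetic far-UV CD basis spectra as sums of Gaussians in wavelength. Each component is [amplitude_mre, center_nm, width_nm]; amplitudes are mean residue ellipticity (deg cm^2 dmol^-1) per unit structure fraction. Shapes are qualitative far-UV signatures of the three aggregate classes, not fitted to any reference protein set.",
  "classes": {
    "helix": [
      [76000.0, 192.0, 8.0],
      [-33000.0, 208.0, 9.0],
      [-36000.0, 222.0, 10.0]
    ],
    "sheet": [
      [35000.0, 196.0, 8.0],
      [-20000.0, 217.0, 10.0]
    ],
    "other": [
      [-42000.0, 198.0, 9.0],
      [3500.0, 220.0, 12.0]
    ]
  }
}
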