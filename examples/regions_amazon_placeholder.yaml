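# SYNTHETIC PLACEHOLDER region file — replace with authoritative vertices.
#
# Region files are lists of named lat/lon boxes consumed by the `compute`
# CLI (--regions) and by climspeed.RegionBox.  The Amazon entry below is a
# rough rectangular stand-in, NOT the IPCC AR5 reference polygon; users
# reproducing published regional statistics must substitute the exact
# vertex list from the report defining their region.
- name: amazon_placeholder_synthetic
  lat_min: -20.0
  lat_max: 12.0
  lon_min: 278.0
  lon_max: 326.0
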