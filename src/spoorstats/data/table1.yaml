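# National land distribution (million ha) immediately before the fast-track
# land-reform programme (2000) and in May 2010.
total_mha: 39.1
areas:
  "2000":
    large_scale_private: 11.7
    small_scale_private: 1.4
    old_resettlement: 3.5
    new_resettlement: 0.0
    communal: 16.4
    parks_and_forest: 5.1
    other: 1.0
  "2010":
    large_scale_private: 3.4
    small_scale_private: 1.4
    old_resettlement: 3.5
    new_resettlement: 7.6
    communal: 16.4
    parks_and_forest: 5.1
    other: 1.7
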