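{
  "version": 1,
  "description": "Closed label vocabulary for anatomical label maps. Axial bone covers vertebrae, scapulae, clavicles, sternum, ribs, sacrum and pelvis; extremity bone covers humeri and femora; the lumbar spine carries its own label (a subset of the axial skeleton) because the diffuse Deauville score is read there.",
  "labels": {
    "background": 0,
    "axial_bone": 1,
    "extremity_bone": 2,
    "skull": 3,
    "liver": 4,
    "muscle": 5,
    "lumbar_spine": 6,
    "mediastinum": 7
  }
}
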