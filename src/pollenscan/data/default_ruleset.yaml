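version: sim-default-1
rules:
  T:
    equivalent_diameter:
    - 34.13367801437214
    - 38.02213952367065
    - 45.79906254226769
    - 49.687524051566214
    mean_opacity:
    - 0.3934416805091745
    - 0.44684965906431173
    - 0.5536656161745862
    - 0.6070735947297234
    rhomboidness:
    - 0.6042016794157681
    - 0.6940879314906268
    - 0.8738604356403441
    - 0.9637466877152028
    vacuole_score:
    - -0.025
    - 0.0
    - 0.007247687236242518
    - 0.03224768723624252
  YM:
    equivalent_diameter:
    - 14.680918823798324
    - 16.361221333175973
    - 19.72182635193127
    - 21.402128861308917
    mean_opacity:
    - 0.1818828960703513
    - 0.23009077079592852
    - 0.32650652024708293
    - 0.3747143949726601
    rhomboidness:
    - -0.10933229720866829
    - 0.0
    - 0.21866459441733657
    - 0.32799689162600487
    vacuole_score:
    - -0.025
    - 0.0
    - 0.015444520861313265
    - 0.04044452086131327
  MM:
    equivalent_diameter:
    - 21.178730202798263
    - 23.05753201093448
    - 26.815135627206917
    - 28.693937435343138
    mean_opacity:
    - 0.38189948873919144
    - 0.4356733973754347
    - 0.5432212146479213
    - 0.5969951232841646
    rhomboidness:
    - -0.08015677543013959
    - 0.0
    - 0.16031355086027918
    - 0.24047032629041876
    vacuole_score:
    - -0.13253978940219321
    - 0.0013712991978146066
    - 0.26919347639783026
    - 0.4031045649978381
  VM:
    equivalent_diameter:
    - 27.775450276921298
    - 30.061220859443413
    - 34.63276202448764
    - 36.91853260700975
    mean_opacity:
    - 0.31111544121998624
    - 0.34354901475576566
    - 0.4084161618273245
    - 0.4408497353631039
    rhomboidness:
    - -0.06749407733646806
    - 0.0
    - 0.13498815467293612
    - 0.20248223200940418
    vacuole_score:
    - 0.975
    - 1.0
    - 1.0
    - 1.025
  YP:
    equivalent_diameter:
    - 31.31882923537934
    - 34.67290634473032
    - 41.381060563432285
    - 44.73513767278327
    mean_opacity:
    - 0.530938103120682
    - 0.5826944990383305
    - 0.6862072908736274
    - 0.7379636867912759
    rhomboidness:
    - -0.060206076422231275
    - 0.0
    - 0.12041215284446255
    - 0.18061822926669382
    vacuole_score:
    - -0.025
    - 0.0
    - 0.041159874192625456
    - 0.06615987419262545
  MP:
    equivalent_diameter:
    - 31.62963784063236
    - 34.61823155695286
    - 40.59541898959385
    - 43.58401270591435
    mean_opacity:
    - 0.8041594871768526
    - 0.8460833248628381
    - 0.9299310002348091
    - 0.9718548379207946
    rhomboidness:
    - -0.06633477626734577
    - 0.0
    - 0.13266955253469154
    - 0.1990043288020373
    vacuole_score:
    - -0.03385704367729663
    - 0.0
    - 0.06771408735459326
    - 0.10157113103188989
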