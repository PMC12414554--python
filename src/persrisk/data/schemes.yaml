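# Published weight schemes for poly-environmental risk scores.
#
# "weight" is added when a factor is present, "absent_weight" (default 0)
# when it is absent.  updated_pers weights are natural-log meta-analytic
# odds ratios stored at the published 3-decimal precision so the score's
# stated maximum (9.18) reproduces exactly; "or" keeps the source odds
# ratio for full-precision rematerialization.

updated_pers:
  description: Updated 14-factor PERS, log-odds weights from recent meta-analyses.
  scaling: normalize_to_14
  band_edges: [1, 2, 3, 4]
  factors:
    winter_birth:        {or: 1.05, weight: 0.049}
    low_gestational_age: {or: 1.35, weight: 0.300}
    low_birth_weight:    {or: 1.53, weight: 0.425}
    ethnic_minority:     {or: 1.82, weight: 0.599}
    urban:               {or: 2.39, weight: 0.871}
    cannabis:            {or: 1.97, weight: 0.678}
    bullied:             {or: 2.28, weight: 0.824}
    emotional_abuse:     {or: 3.40, weight: 1.224}
    physical_abuse:      {or: 2.95, weight: 1.082}
    sexual_abuse:        {or: 2.38, weight: 0.867}
    high_paternal_age:   {or: 1.28, weight: 0.247}
    parental_divorce:    {or: 1.53, weight: 0.425}
    parental_smi:        {or: 3.94, weight: 1.371}
    parental_death:      {or: 1.24, weight: 0.215}

p_pers:
  description: >
    Historical 9-factor log-odds scheme (neglect unavailable, leaving the
    eight factors below).
  scaling: none
  band_edges: null
  factors:
    winter_or_spring_birth: {weight: 0.068}
    low_birth_weight:       {weight: 0.69}
    urban:                  {weight: 0.54}
    cannabis:               {weight: 0.56}
    physical_abuse:         {weight: 1.08}
    sexual_abuse:           {weight: 0.87}
    high_paternal_age:      {weight: 0.25}
    parental_death:         {weight: 0.53}

m_pers:
  description: >
    Historical 6-factor integer-point scheme; some absent states carry
    negative points, so the score can be negative and no bands are defined.
  scaling: none
  band_edges: null
  factors:
    ethnic_minority:         {weight: 2.5, absent_weight: -0.5}
    urban:                   {weight: 1.0, absent_weight: -1.5}
    paternal_age_40_50:      {weight: 0.5}
    low_birth_weight:        {weight: 2.0}
    cannabis:                {weight: 3.0, absent_weight: -1.0}
    any_childhood_adversity: {weight: 2.5}
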