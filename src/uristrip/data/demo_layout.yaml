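template:
  width: 272
  height: 352
window: 10
metadata:
  patch_size: 18
  texture_seed: 20220601
  synthetic: true
analytes:
- name: protein
  pad_center:
  - 225.0
  - 41.0
  grades:
  - label: '-'
    color:
    - 190
    - 186
    - 104
    center:
    - 41.0
    - 41.0
  - label: +-
    color:
    - 173
    - 181
    - 106
    center:
    - 65.0
    - 41.0
  - label: 1+
    color:
    - 149
    - 171
    - 112
    center:
    - 89.0
    - 41.0
  - label: 2+
    color:
    - 118
    - 158
    - 120
    center:
    - 113.0
    - 41.0
  - label: 3+
    color:
    - 86
    - 144
    - 125
    center:
    - 137.0
    - 41.0
  - label: 4+
    color:
    - 56
    - 128
    - 128
    center:
    - 161.0
    - 41.0
- name: glucose
  pad_center:
  - 225.0
  - 65.0
  grades:
  - label: '-'
    color:
    - 96
    - 152
    - 152
    center:
    - 41.0
    - 65.0
  - label: +-
    color:
    - 112
    - 149
    - 120
    center:
    - 65.0
    - 65.0
  - label: 1+
    color:
    - 130
    - 141
    - 88
    center:
    - 89.0
    - 65.0
  - label: 2+
    color:
    - 141
    - 120
    - 64
    center:
    - 113.0
    - 65.0
  - label: 3+
    color:
    - 136
    - 92
    - 48
    center:
    - 137.0
    - 65.0
  - label: 4+
    color:
    - 120
    - 64
    - 36
    center:
    - 161.0
    - 65.0
- name: urobilinogen
  pad_center:
  - 225.0
  - 89.0
  grades:
  - label: '0.1'
    color:
    - 200
    - 184
    - 168
    center:
    - 41.0
    - 89.0
  - label: '2'
    color:
    - 196
    - 160
    - 148
    center:
    - 65.0
    - 89.0
  - label: '4'
    color:
    - 188
    - 128
    - 120
    center:
    - 89.0
    - 89.0
  - label: '8'
    color:
    - 172
    - 88
    - 92
    center:
    - 113.0
    - 89.0
- name: bilirubin
  pad_center:
  - 225.0
  - 113.0
  grades:
  - label: '-'
    color:
    - 200
    - 192
    - 160
    center:
    - 41.0
    - 113.0
  - label: 1+
    color:
    - 192
    - 176
    - 136
    center:
    - 65.0
    - 113.0
  - label: 2+
    color:
    - 180
    - 156
    - 112
    center:
    - 89.0
    - 113.0
  - label: 3+
    color:
    - 164
    - 132
    - 92
    center:
    - 113.0
    - 113.0
- name: ketone
  pad_center:
  - 225.0
  - 137.0
  grades:
  - label: '-'
    color:
    - 196
    - 184
    - 160
    center:
    - 41.0
    - 137.0
  - label: +-
    color:
    - 184
    - 160
    - 152
    center:
    - 65.0
    - 137.0
  - label: 1+
    color:
    - 164
    - 128
    - 140
    center:
    - 89.0
    - 137.0
  - label: 2+
    color:
    - 136
    - 88
    - 120
    center:
    - 113.0
    - 137.0
  - label: 3+
    color:
    - 104
    - 48
    - 92
    center:
    - 137.0
    - 137.0
- name: specific gravity
  pad_center:
  - 225.0
  - 161.0
  grades:
  - label: '1.000'
    color:
    - 24
    - 72
    - 96
    center:
    - 41.0
    - 161.0
  - label: '1.005'
    color:
    - 48
    - 88
    - 92
    center:
    - 65.0
    - 161.0
  - label: '1.010'
    color:
    - 76
    - 104
    - 84
    center:
    - 89.0
    - 161.0
  - label: '1.015'
    color:
    - 104
    - 120
    - 76
    center:
    - 113.0
    - 161.0
  - label: '1.020'
    color:
    - 132
    - 136
    - 68
    center:
    - 137.0
    - 161.0
  - label: '1.025'
    color:
    - 160
    - 148
    - 60
    center:
    - 161.0
    - 161.0
  - label: '1.030'
    color:
    - 180
    - 160
    - 52
    center:
    - 185.0
    - 161.0
- name: occult blood
  pad_center:
  - 225.0
  - 185.0
  grades:
  - label: '-'
    color:
    - 188
    - 176
    - 80
    center:
    - 41.0
    - 185.0
  - label: +-
    color:
    - 168
    - 168
    - 84
    center:
    - 65.0
    - 185.0
  - label: 1+
    color:
    - 120
    - 148
    - 92
    center:
    - 89.0
    - 185.0
  - label: 2+
    color:
    - 72
    - 120
    - 96
    center:
    - 113.0
    - 185.0
  - label: 3+
    color:
    - 32
    - 88
    - 88
    center:
    - 137.0
    - 185.0
- name: pH
  pad_center:
  - 225.0
  - 209.0
  grades:
  - label: '5'
    color:
    - 188
    - 120
    - 56
    center:
    - 41.0
    - 209.0
  - label: '6'
    color:
    - 184
    - 148
    - 64
    center:
    - 65.0
    - 209.0
  - label: '7'
    color:
    - 152
    - 156
    - 72
    center:
    - 89.0
    - 209.0
  - label: '8'
    color:
    - 96
    - 140
    - 104
    center:
    - 113.0
    - 209.0
  - label: '9'
    color:
    - 48
    - 112
    - 128
    center:
    - 137.0
    - 209.0
- name: leukocytes
  pad_center:
  - 225.0
  - 233.0
  grades:
  - label: '-'
    color:
    - 200
    - 192
    - 176
    center:
    - 41.0
    - 233.0
  - label: +-
    color:
    - 192
    - 176
    - 168
    center:
    - 65.0
    - 233.0
  - label: 1+
    color:
    - 176
    - 148
    - 156
    center:
    - 89.0
    - 233.0
  - label: 2+
    color:
    - 152
    - 112
    - 136
    center:
    - 113.0
    - 233.0
  - label: 3+
    color:
    - 120
    - 76
    - 116
    center:
    - 137.0
    - 233.0
- name: nitrite
  pad_center:
  - 225.0
  - 257.0
  grades:
  - label: '-'
    color:
    - 200
    - 196
    - 188
    center:
    - 41.0
    - 257.0
  - label: +
    color:
    - 192
    - 136
    - 144
    center:
    - 65.0
    - 257.0
- name: creatinine
  pad_center:
  - 225.0
  - 281.0
  grades:
  - label: '10'
    color:
    - 196
    - 172
    - 96
    center:
    - 41.0
    - 281.0
  - label: '50'
    color:
    - 184
    - 148
    - 80
    center:
    - 65.0
    - 281.0
  - label: '100'
    color:
    - 168
    - 120
    - 68
    center:
    - 89.0
    - 281.0
  - label: '200'
    color:
    - 148
    - 92
    - 56
    center:
    - 113.0
    - 281.0
  - label: '300'
    color:
    - 128
    - 68
    - 44
    center:
    - 137.0
    - 281.0
- name: albumin
  pad_center:
  - 225.0
  - 305.0
  grades:
  - label: '10'
    color:
    - 180
    - 184
    - 144
    center:
    - 41.0
    - 305.0
  - label: '30'
    color:
    - 148
    - 168
    - 132
    center:
    - 65.0
    - 305.0
  - label: '80'
    color:
    - 112
    - 148
    - 124
    center:
    - 89.0
    - 305.0
  - label: '150'
    color:
    - 76
    - 128
    - 120
    center:
    - 113.0
    - 305.0
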