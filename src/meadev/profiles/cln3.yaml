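genotype_label: cln3
anchors:
  div:
  - 4
  - 5
  - 6
  - 7
  - 8
  - 9
  - 10
  - 11
  - 12
  - 13
  - 14
  - 15
  - 16
  - 17
  - 18
  - 19
  - 20
  - 21
  - 22
  - 23
  - 24
  - 25
  - 26
  - 27
  - 28
  - 29
  - 30
  - 31
  - 32
  - 33
  - 34
  - 35
  - 36
  - 37
  - 38
  - 39
  - 40
  - 41
  - 42
  tonic_rate:
  - 0.77504
  - 0.850968
  - 0.925668
  - 0.942383
  - 0.997557
  - 1.032864
  - 0.957617
  - 0.611606
  - 0.8189
  - 1.010782
  - 1.119597
  - 1.167723
  - 1.212452
  - 1.194912
  - 1.234043
  - 1.276241
  - 1.565141
  - 1.227263
  - 1.177717
  - 1.087408
  - 1.401161
  - 1.032359
  - 1.080386
  - 1.092488
  - 1.53252
  - 1.545419
  - 1.554147
  - 1.230716
  - 1.309539
  - 1.276548
  - 1.564277
  - 1.300382
  - 1.322783
  - 1.351287
  - 1.384317
  - 1.463099
  - 1.500379
  - 1.537683
  - 1.573434
  burst_rate:
  - 0.341549
  - 1.36847
  - 2.395392
  - 3.422313
  - 4.449235
  - 5.476157
  - 6.503078
  - 7.53
  - 7.3
  - 6.15
  - 5.0
  - 4.63
  - 4.26
  - 3.89
  - 3.52
  - 3.15
  - 2.78
  - 2.84
  - 2.9
  - 2.96
  - 3.451253
  - 3.08
  - 3.14
  - 3.2
  - 3.164574
  - 3.12
  - 3.08
  - 3.04
  - 3.0
  - 2.96
  - 2.92
  - 2.88
  - 2.84
  - 2.8
  - 2.76
  - 2.72
  - 2.68
  - 2.64
  - 2.6
  burst_duration:
  - 0.1
  - 0.106667
  - 0.113333
  - 0.12
  - 0.126667
  - 0.133333
  - 0.14
  - 0.2
  - 0.207143
  - 0.214286
  - 0.221429
  - 0.228571
  - 0.235714
  - 0.242857
  - 0.25
  - 0.257143
  - 0.264286
  - 0.271429
  - 0.278571
  - 0.285714
  - 0.292857
  - 0.3
  - 0.297059
  - 0.294118
  - 0.291176
  - 0.288235
  - 0.285294
  - 0.282353
  - 0.279412
  - 0.276471
  - 0.273529
  - 0.270588
  - 0.267647
  - 0.264706
  - 0.261765
  - 0.258824
  - 0.255882
  - 0.252941
  - 0.25
  intra_burst_isi:
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  active_electrode_prob:
  - 0.136058
  - 0.162362
  - 0.188666
  - 0.214971
  - 0.241275
  - 0.293457
  - 0.345638
  - 0.397819
  - 0.45
  - 0.45625
  - 0.4625
  - 0.46875
  - 0.475
  - 0.48125
  - 0.4875
  - 0.49375
  - 0.5
  - 0.5105
  - 0.521
  - 0.5315
  - 0.542
  - 0.5525
  - 0.563
  - 0.5735
  - 0.584
  - 0.5945
  - 0.605
  - 0.6155
  - 0.626
  - 0.5984
  - 0.5708
  - 0.5432
  - 0.5156
  - 0.488
  - 0.4604
  - 0.4328
  - 0.4052
  - 0.3776
  - 0.35
  network_burst_rate:
  - 0.0
  - 0.0125
  - 0.025
  - 0.0375
  - 0.05
  - 0.124375
  - 0.19875
  - 0.273125
  - 0.3475
  - 0.421875
  - 0.49625
  - 0.570625
  - 0.645
  - 0.719375
  - 0.79375
  - 0.868125
  - 0.9425
  - 1.016875
  - 1.09125
  - 1.165625
  - 1.24
  - 1.176667
  - 1.113333
  - 1.05
  - 0.986667
  - 0.923333
  - 0.86
  - 0.796667
  - 0.733333
  - 0.67
  - 0.606667
  - 0.543333
  - 0.48
  - 0.416667
  - 0.353333
  - 0.29
  - 0.226667
  - 0.163333
  - 0.1
  network_burst_duration:
  - 0.3
  - 0.383
  - 0.466
  - 0.549
  - 0.632
  - 0.715
  - 0.798
  - 0.881
  - 0.964
  - 1.047
  - 1.13
  - 1.213
  - 1.296
  - 1.379
  - 1.462
  - 1.545
  - 1.628
  - 1.711
  - 1.794
  - 1.877
  - 1.96
  - 2.011111
  - 2.062222
  - 2.113333
  - 2.164444
  - 2.215556
  - 2.266667
  - 2.317778
  - 2.368889
  - 2.42
  - 2.317778
  - 2.215556
  - 2.113333
  - 2.011111
  - 1.908889
  - 1.806667
  - 1.704444
  - 1.602222
  - 1.5
  network_participation:
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 0.25
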