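scale_name,item_index
GDS30,1
GDS30,2
GDS30,3
GDS30,4
GDS30,5
GDS30,6
GDS30,7
GDS30,8
GDS30,9
GDS30,10
GDS30,11
GDS30,12
GDS30,13
GDS30,14
GDS30,15
GDS30,16
GDS30,17
GDS30,18
GDS30,19
GDS30,20
GDS30,21
GDS30,22
GDS30,23
GDS30,24
GDS30,25
GDS30,26
GDS30,27
GDS30,28
GDS30,29
GDS30,30
GDS15,1
GDS15,2
GDS15,3
GDS15,4
GDS15,7
GDS15,8
GDS15,9
GDS15,10
GDS15,12
GDS15,14
GDS15,15
GDS15,17
GDS15,21
GDS15,22
GDS15,23
GDS4,1
GDS4,3
GDS4,9
GDS4,15
GDS10-IRT,1
GDS10-IRT,4
GDS10-IRT,6
GDS10-IRT,10
GDS10-IRT,11
GDS10-IRT,16
GDS10-IRT,17
GDS10-IRT,21
GDS10-IRT,22
GDS10-IRT,25
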