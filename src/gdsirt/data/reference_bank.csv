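item_id,label,a,b,item_auc
1,Satisfied with life (R),1.70,0.83,0.694
2,Dropped activities/interests,0.78,-0.55,0.615
3,Feel that your life is empty,1.60,0.25,0.682
4,Often get bored,1.74,0.48,0.709
5,Hopeful about the future (R),0.97,-0.30,0.607
6,Bothered by thoughts,1.62,0.78,0.669
7,Good spirits most of time (R),1.29,1.10,0.716
8,Afraid something bad will happen,1.28,0.97,0.657
9,Happy most of the time (R),1.55,0.85,0.704
10,Feel helpless,1.84,0.87,0.712
11,Get restless and fidgety,1.88,1.27,0.711
12,Prefer to stay at home,0.61,1.42,0.657
13,Worry about the future,1.42,0.56,0.657
14,More memory problems than most,0.90,1.51,0.654
15,Wonderful to be alive now (R),1.24,1.26,0.654
16,Downhearted and blue,2.47,0.60,0.744
17,Feel pretty worthless,1.93,0.92,0.707
18,Worry about the past,1.53,1.33,0.667
19,Find life very exciting (R),1.43,-0.07,0.671
20,Hard to start new projects,0.65,-0.82,0.610
21,Feel full of energy (R),1.68,-0.07,0.695
22,Situation is hopeless,2.31,1.29,0.676
23,Others better off than you,1.03,1.08,0.653
24,Upset over little things,1.59,0.63,0.696
25,Frequently feel like crying,2.29,1.20,0.738
26,Trouble concentrating,1.06,0.80,0.679
27,Enjoy getting up in the morning (R),0.84,1.80,0.671
28,Avoid social gatherings,0.75,2.26,0.612
29,Easy to make decisions (R),0.20,0.32,0.554
30,Mind as clear as it used to be (R),0.86,-0.22,0.676
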