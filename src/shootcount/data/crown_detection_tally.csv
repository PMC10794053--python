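image_id,total,yolox_correct,yolox_false,yolox_missed,yolov5_correct,yolov5_false,yolov5_missed,efficientnet_correct,efficientnet_false,efficientnet_missed,faster_rcnn_correct,faster_rcnn_false,faster_rcnn_missed
1,13,13,0,0,13,0,0,13,0,0,8,3,5
2,15,15,0,0,15,0,0,15,0,0,9,12,6
3,10,10,0,0,10,2,0,10,3,0,7,2,3
4,5,5,0,0,5,1,0,5,4,0,4,4,1
5,5,5,0,0,5,1,0,5,5,0,4,1,1
6,2,2,0,0,1,0,1,2,3,0,2,4,0
7,6,6,1,0,2,0,4,6,1,0,5,2,1
8,7,7,1,1,3,0,4,7,1,0,5,2,2
9,8,6,0,2,3,0,5,8,0,0,4,2,4
10,5,5,0,0,5,2,0,5,4,0,4,8,1
11,8,8,1,0,8,0,0,8,0,0,6,11,2
12,9,9,0,0,9,1,0,9,1,0,5,5,4
13,14,14,0,0,14,1,0,14,4,0,6,3,8
14,16,16,0,0,16,0,0,16,2,0,12,6,4
15,12,12,0,0,12,0,0,12,2,0,6,4,6
16,17,17,0,0,17,0,0,16,1,0,10,5,7
17,11,11,0,0,11,1,0,11,1,0,5,4,6
18,6,6,0,0,6,0,0,6,0,0,5,7,1
19,7,7,3,0,7,2,0,7,5,0,5,4,2
20,13,13,1,0,13,0,0,13,0,0,4,4,9
21,24,24,0,0,24,0,0,24,1,0,10,9,14
22,36,35,1,1,31,0,5,34,4,2,5,8,31
23,10,9,1,0,8,0,2,10,2,0,6,7,4
24,8,8,1,0,8,0,0,8,1,0,3,4,5
25,19,16,1,3,15,0,4,19,2,0,4,5,15
26,17,17,1,0,16,0,1,18,1,0,5,4,12
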